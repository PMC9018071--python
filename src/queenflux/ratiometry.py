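"""From raw two-channel stacks to QC'd, calibrated per-cell ATP time series.

The sensor is excited at 410 nm (ATP-sensitive) and 490 nm (reference); the
per-frame ratio of the mean in-cell intensities, ex410/ex490, is the cell's
ATP readout and is converted to mM through a user-supplied calibration.

Occasional single-frame acquisition failures make exactly one of the two
channel signals unusually intense in one frame (historically about once in 70
frames).  Such frames are flagged by a robust outlier rule on each channel
and the affected ratio values are repaired by averaging the previous and next
frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .calibration import CalibrationCurve
from .traces import ChannelTraces, RatioTrace

__all__ = [
    "max_project",
    "extract_cell_trace",
    "compute_ratio_trace",
    "detect_frame_errors",
    "correct_frame_errors",
    "ratio_to_atp",
    "population_summary",
    "PopulationSummary",
]


def max_project(zstack) -> np.ndarray:
    """Pixelwise maximum-intensity projection over the leading z axis."""
    stack = np.asarray(zstack)
    if stack.ndim < 3:
        if stack.ndim == 2:
            return stack.copy()
        raise ValueError("max_project expects (Z, Y, X) or a 2-D image")
    if stack.shape[0] == 0:
        raise ValueError("cannot project an empty z-stack")
    return stack.max(axis=0)


def extract_cell_trace(stack, label_mask, cell_id, frame_interval: float) -> ChannelTraces:
    """Per-frame mean channel intensities over one cell's mask pixels.

    ``stack`` has shape (T, C, Y, X) with channel 0 = ex410 and channel 1 =
    ex490 (or (T, Y, X) pairs passed per channel elsewhere).
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 4 or arr.shape[1] < 2:
        raise ValueError("stack must be (T, C>=2, Y, X) with channels [ex410, ex490]")
    mask = np.asarray(label_mask)
    lab = int(cell_id)
    sel = mask == lab
    if not sel.any():
        raise ValueError(f"cell_id {cell_id!r} has no pixels in the label mask")
    ex410 = arr[:, 0][:, sel].mean(axis=1)
    ex490 = arr[:, 1][:, sel].mean(axis=1)
    return ChannelTraces(
        cell_id=str(cell_id), ex410=ex410, ex490=ex490, frame_interval=frame_interval
    )


def compute_ratio_trace(channels: ChannelTraces) -> RatioTrace:
    """Per-frame sensor ratio ex410/ex490.

    The ratio is invariant to any common gain on the two channels.  Frames
    with a non-positive reference signal cannot form a ratio and are rejected
    rather than silently dropped.
    """
    bad = np.nonzero(channels.ex490 <= 0)[0]
    if bad.size:
        raise ValueError(
            f"cell {channels.cell_id}: non-positive ex490 at frames {bad.tolist()[:10]}"
        )
    return RatioTrace(
        cell_id=channels.cell_id,
        ratio=channels.ex410 / channels.ex490,
        frame_interval=channels.frame_interval,
    )


def _running_median_residuals(x: np.ndarray, window: int) -> tuple[np.ndarray, float]:
    med = median_filter(x, size=window, mode="nearest")
    resid = x - med
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * float(mad)
    return resid, robust_sd


def detect_frame_errors(
    channels: ChannelTraces, threshold_sd: float = 5.0, window: int = 7
) -> list[int]:
    """Flag frames where exactly one channel is unusually intense.

    Each channel is compared against its running median (centred window,
    default 7 frames); a frame is anomalous in a channel when the positive
    deviation exceeds ``threshold_sd`` robust standard deviations (MAD-based).
    Only frames anomalous in exactly one channel are flagged: a genuine ATP
    change moves the ATP-sensitive channel *down* over several frames, and a
    global illumination glitch moves both channels together — neither matches
    the single-channel, single-frame intense signature of an exposure error.
    """
    if channels.n_frames < 5:
        raise ValueError("frame-error detection needs at least 5 frames")
    flags_per_channel = []
    for x in (channels.ex410, channels.ex490):
        resid, robust_sd = _running_median_residuals(x, window)
        if robust_sd == 0:
            scale = float(np.std(x))
            robust_sd = scale if scale > 0 else np.inf
        flags_per_channel.append(resid > threshold_sd * robust_sd)
    a, b = flags_per_channel
    return [int(k) for k in np.nonzero(a ^ b)[0]]


def correct_frame_errors(ratio_trace: RatioTrace, flagged) -> RatioTrace:
    """Replace each flagged frame's ratio by the mean of its neighbours.

    Interior flagged frames become (previous + next) / 2 using unflagged (or
    already-corrected) neighbours; flagged first/last frames copy their
    nearest valid neighbour.  Runs of adjacent flagged frames are corrected
    iteratively from the outside in, with a warning, since the repair then
    leans on repaired values.
    """
    flagged = sorted(set(int(k) for k in flagged))
    r = ratio_trace.ratio.copy()
    n = r.size
    if any(k < 0 or k >= n for k in flagged):
        raise ValueError("flagged frame index out of range")
    if not flagged:
        return replace(ratio_trace, ratio=r)
    flagged_set = set(flagged)
    if any(k + 1 in flagged_set for k in flagged):
        warnings.warn(
            "adjacent flagged frames corrected iteratively outside-in", stacklevel=2
        )
    pending = set(flagged)
    while pending:
        progressed = False
        for k in sorted(pending):
            left_ok = k - 1 >= 0 and (k - 1) not in pending
            right_ok = k + 1 < n and (k + 1) not in pending
            if left_ok and right_ok:
                r[k] = 0.5 * (r[k - 1] + r[k + 1])
            elif left_ok:  # trailing edge or right side still pending
                r[k] = r[k - 1]
            elif right_ok:  # leading edge or left side still pending
                r[k] = r[k + 1]
            else:
                continue
            pending.discard(k)
            progressed = True
        if not progressed:  # every frame flagged: nothing valid to lean on
            raise ValueError("cannot correct: no unflagged frames available")
    corrected = tuple(sorted(set(ratio_trace.corrected_frames) | flagged_set))
    return replace(ratio_trace, ratio=r, corrected_frames=corrected)


def ratio_to_atp(ratio_trace: RatioTrace, calibration: CalibrationCurve) -> RatioTrace:
    """Fill the mM ATP series from the ratio via the calibration curve."""
    lo, hi = calibration._clipped_range()
    out_of_range = (ratio_trace.ratio < lo) | (ratio_trace.ratio > hi)
    if out_of_range.any():
        warnings.warn(
            f"cell {ratio_trace.cell_id}: {int(out_of_range.sum())} ratio values outside "
            "the calibration range were clipped",
            stacklevel=2,
        )
    atp = np.asarray(calibration.atp_from_ratio(ratio_trace.ratio))
    return replace(ratio_trace, atp=atp)


@dataclass(frozen=True)
class PopulationSummary:
    mean: float
    sd: float
    cv: float  # SD / mean; NaN when the mean is zero
    n: int


def population_summary(values) -> PopulationSummary:
    """Mean, SD and coefficient of variance of per-cell ATP readouts.

    ``values`` is either a sequence of per-cell scalars (e.g. time-averaged
    ratios or single-timepoint readouts) or a sequence of traces, in which
    case each cell contributes its time-mean ratio.
    """
    vals = [
        float(np.mean(v.ratio)) if isinstance(v, RatioTrace) else float(v) for v in values
    ]
    if len(vals) < 2:
        raise ValueError("population_summary requires at least 2 cells")
    arr = np.asarray(vals)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    return PopulationSummary(mean=mean, sd=sd, cv=cv, n=arr.size)
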