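"""Per-cell ATP-dynamics statistics and the dip / shallow-dip / shift / stable classifier.

The classifier deliberately mirrors fixed-threshold rules rather than learned
changepoints: a transient decrease in the mean sensor ratio of more than 0.5
ratio units spanning more than 2 frames is an *ATP dip*; a decrease of
0.33-0.5 is a *shallow dip*; a decrease of more than 0.33 that never recovers
within the observation period is an *ATP shift*; a cell with no qualifying
event observed for at least twice its strain's doubling time is *stable*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClassifierThresholds
from .traces import RatioTrace

__all__ = [
    "LagDiffResult",
    "DipEvent",
    "TraceClassification",
    "label_event",
    "lag_diff",
    "max_diff_profile",
    "detect_dip_events",
    "classify_trace",
    "cohort_classify",
]

LABELS = ("stable", "dip", "shallow_dip", "shift")


@dataclass(frozen=True)
class LagDiffResult:
    """Lagged ratio differences d(t, l) = ratio_t - ratio_{t-l} and their extremes.

    ``max_abs`` is the largest magnitude of change; ``max_drop`` the largest
    decrease (reported as a positive magnitude, 0 if the trace never falls).
    """

    lag: int
    diffs: np.ndarray
    max_abs: float
    max_drop: float


@dataclass(frozen=True)
class DipEvent:
    """One detected ATP-depletion episode.

    ``depth`` is baseline-to-nadir in ratio units, with the baseline frozen at
    event entry.  ``end`` is the first recovered frame (exclusive event
    bound), or None for an unrecovered shift.
    """

    onset: int
    nadir: int
    end: int | None
    baseline: float
    depth: float
    duration_frames: int
    frame_interval: float
    recovered: bool

    @property
    def duration_min(self) -> float:
        return self.duration_frames * self.frame_interval


@dataclass
class TraceClassification:
    label: str
    events: list[DipEvent] = field(default_factory=list)
    observation_span_min: float = 0.0
    qualifies_for_stable: bool = False


def label_event(
    depth: float,
    duration_frames: int,
    recovered: bool,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Definitional predicate mapping one depletion event to its class.

    Returns "dip", "shallow_dip", "shift", or "none" (the event does not
    qualify as any ATP-dynamics event).  A recovered decrease deeper than the
    dip threshold but too short to span more than ``min_frames`` frames is
    graded as a shallow dip: it exceeds the shallow threshold but fails the
    duration requirement of the deep class.
    """
    thr = thresholds or ClassifierThresholds()
    if depth <= thr.shallow:
        return "none"
    if not recovered:
        return "shift"
    if depth > thr.deep and duration_frames > thr.min_frames:
        return "dip"
    return "shallow_dip"


def lag_diff(trace: RatioTrace | np.ndarray, l: int) -> LagDiffResult:
    """Lagged differences of the ratio trace at lag ``l`` frames."""
    r = trace.ratio if isinstance(trace, RatioTrace) else np.asarray(trace, dtype=float)
    T = r.size
    if not 1 <= l < T:
        raise ValueError(f"lag must satisfy 1 <= l < {T}, got {l}")
    diffs = r[l:] - r[:-l]
    max_abs = float(np.max(np.abs(diffs)))
    max_drop = float(max(0.0, -np.min(diffs)))
    return LagDiffResult(lag=l, diffs=diffs, max_abs=max_abs, max_drop=max_drop)


def max_diff_profile(trace: RatioTrace | np.ndarray, l_values) -> pd.DataFrame:
    """Maximum ratio change per lag, for lag-robustness profiles.

    The extreme lagged change of a stable cell stays well below the dip
    threshold at every lag, whereas a cell with a deep dip exceeds it at every
    lag, which is what makes the fixed-threshold definition lag-insensitive.
    """
    rows = []
    for l in l_values:
        res = lag_diff(trace, int(l))
        rows.append({"l": int(l), "max_abs": res.max_abs, "max_drop": res.max_drop})
    return pd.DataFrame(rows)


def _robust_nadir(r: np.ndarray, onset: int, end: int) -> tuple[int, float]:
    """Nadir of the event frames [onset, end).

    For events spanning >= 3 frames the nadir level is the minimum of the
    centred 3-frame mean over interior event frames, which suppresses the
    single-frame noise minimum while remaining exact on plateau-shaped events.
    """
    seg = r[onset:end]
    k_raw = int(np.argmin(seg)) + onset
    if end - onset >= 3:
        means = np.convolve(seg, np.ones(3) / 3.0, mode="valid")  # centres onset+1..end-2
        j = int(np.argmin(means))
        return j + onset + 1, float(means[j])
    return k_raw, float(seg.min())


def detect_dip_events(
    trace: RatioTrace,
    thresholds: ClassifierThresholds | None = None,
) -> list[DipEvent]:
    """Detect transient decreases of the mean sensor ratio.

    A candidate event opens when the ratio falls more than ``enter_delta``
    below the running-median baseline (median of the preceding
    ``baseline_window`` frames, frozen at entry), and closes as recovered when
    the ratio returns above baseline - exit_frac * depth.  An event still open
    at the last frame is unrecovered (a shift candidate).
    """
    thr = thresholds or ClassifierThresholds()
    r = trace.ratio
    n = r.size
    w = thr.baseline_window
    if n <= w:
        raise ValueError(f"trace has {n} frames; needs more than baseline_window={w}")

    events: list[DipEvent] = []
    i = w
    while i < n:
        baseline = float(np.median(r[i - w : i]))
        if r[i] < baseline - thr.enter_delta:
            onset = i
            j = i
            end: int | None = None
            while j < n:
                raw_depth = baseline - r[onset : j + 1].min()
                if r[j] >= baseline - thr.exit_frac * raw_depth:
                    end = j
                    break
                j += 1
            if end is None:
                nadir, nadir_val = _robust_nadir(r, onset, n)
                events.append(
                    DipEvent(
                        onset=onset,
                        nadir=nadir,
                        end=None,
                        baseline=baseline,
                        depth=baseline - nadir_val,
                        duration_frames=n - onset,
                        frame_interval=trace.frame_interval,
                        recovered=False,
                    )
                )
                break
            nadir, nadir_val = _robust_nadir(r, onset, end)
            events.append(
                DipEvent(
                    onset=onset,
                    nadir=nadir,
                    end=end,
                    baseline=baseline,
                    depth=baseline - nadir_val,
                    duration_frames=end - onset,
                    frame_interval=trace.frame_interval,
                    recovered=True,
                )
            )
            i = end + 1
        else:
            i += 1
    return events


def classify_trace(
    trace: RatioTrace,
    events: list[DipEvent] | None = None,
    thresholds: ClassifierThresholds | None = None,
    doubling_time_min: float | None = None,
) -> TraceClassification:
    """Classify one cell's ATP dynamics from its detected events.

    Precedence when several event classes co-occur: dip > shift > shallow dip
    (cohort fractions pool dip and shift, so precedence only affects
    sub-labels).  A cell with no qualifying event is "stable" only when it was
    observed for at least twice the strain doubling time; shorter event-free
    traces are labelled "indeterminate_stable" and excluded from fractions.
    """
    thr = thresholds or ClassifierThresholds()
    if events is None:
        events = detect_dip_events(trace, thr)
    kinds = [label_event(e.depth, e.duration_frames, e.recovered, thr) for e in events]
    qualifying = [e for e, k in zip(events, kinds) if k != "none"]
    span = trace.span_min
    if "dip" in kinds:
        label = "dip"
    elif "shift" in kinds:
        label = "shift"
    elif "shallow_dip" in kinds:
        label = "shallow_dip"
    else:
        if doubling_time_min is None:
            raise ValueError(
                "doubling_time_min is required to call an event-free trace stable"
            )
        label = "stable" if span >= 2 * doubling_time_min else "indeterminate_stable"
    return TraceClassification(
        label=label,
        events=qualifying,
        observation_span_min=span,
        qualifies_for_stable=(label == "stable"),
    )


def cohort_classify(
    traces: list[RatioTrace],
    thresholds: ClassifierThresholds | None = None,
    doubling_time_min: float = 288.0,
) -> tuple[dict[str, float], pd.DataFrame, pd.DataFrame]:
    """Classify a cohort; returns (fractions, per-cell labels, per-event table).

    Fractions are over classifiable cells (indeterminate event-free short
    traces excluded) and sum to 1.
    """
    if not traces:
        raise ValueError("cohort_classify requires at least one trace")
    rows, ev_rows = [], []
    for tr in traces:
        cls = classify_trace(tr, None, thresholds, doubling_time_min)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "label": cls.label,
                "n_events": len(cls.events),
                "span_min": cls.observation_span_min,
            }
        )
        for e in cls.events:
            ev_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "onset_frame": e.onset,
                    "onset_min": e.onset * e.frame_interval,
                    "depth": e.depth,
                    "duration_frames": e.duration_frames,
                    "duration_min": e.duration_min,
                    "recovered": e.recovered,
                }
            )
    labels = pd.DataFrame(rows)
    events = pd.DataFrame(
        ev_rows,
        columns=[
            "cell_id",
            "onset_frame",
            "onset_min",
            "depth",
            "duration_frames",
            "duration_min",
            "recovered",
        ],
    )
    classifiable = labels[labels["label"] != "indeterminate_stable"]
    if len(classifiable) == 0:
        warnings.warn("no classifiable cells (all spans too short)")
        fractions = {lab: float("nan") for lab in LABELS}
    else:
        counts = classifiable["label"].value_counts()
        fractions = {lab: float(counts.get(lab, 0)) / len(classifiable) for lab in LABELS}
    return fractions, labels, events
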