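"""Aggregate-foci detection and the pre-dip-regression RMSD statistic.

Foci of the aggregate reporter are detected as local intensity maxima whose
topographic prominence — the height of the peak above the highest saddle
connecting it to any higher peak, under 8-connectivity — exceeds a noise
tolerance (default 4000 camera units).  This reproduces the noise-tolerance
semantics of the FindMaxima-style detectors used interactively in image
analysis software, with plateau maxima reduced to a single centroid point.

The accumulation statistic: reporter intensity in cells with stable ATP rises
linearly with time, so intensity before a detected ATP dip is fit by ordinary
least squares and the root-mean-square deviation (RMSD) from that line is
computed *before* the dip and over cumulative windows *after* it.  Fold
changes after/before quantify how much the accumulation departs from the
pre-dip linear regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traces import AggregationTrace

__all__ = [
    "Focus",
    "LinearFit",
    "RmsdResult",
    "find_maxima",
    "focus_mean_intensity",
    "foci_fraction",
    "cell_mean_intensity_trace",
    "fit_pre_dip_regression",
    "rmsd",
    "rmsd_timecourse",
    "expected_null_fold",
    "cohort_rmsd_report",
]

# 3-pixel-diameter circle rasterized as the centre pixel plus its 4-neighbours
# (the 5-pixel plus used by ImageJ-style oval measurement at diameter 3).
_CIRCLE3_OFFSETS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))

_NEIGHBORS8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class Focus:
    """One detected aggregate focus."""

    position: tuple[int, int]  # (row, col)
    peak_value: float
    prominence: float
    mean_intensity_3px: float
    frame: int | None = None
    cell_id: str | None = None
    edge: bool = False


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line intensity = slope * t + intercept."""

    slope: float  # intensity / minute
    intercept: float
    pearson_r: float
    fit_window: tuple[int, int]  # [start_frame, end_frame) used for the fit

    def predict(self, time_min) -> np.ndarray:
        return self.slope * np.asarray(time_min, dtype=float) + self.intercept


@dataclass
class RmsdResult:
    """Pre/post-dip RMSD of reporter intensity about the pre-dip line."""

    rmsd_before: float
    rmsd_after: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    max_fold: float = float("nan")
    pre_dip_span_min: float = 0.0
    partial: bool = False  # horizon extended past the end of the trace


def find_maxima(image, noise_tolerance: float, frame: int | None = None) -> list[Focus]:
    """Detect local maxima with prominence exceeding ``noise_tolerance``.

    Prominence is computed exactly by a union-find sweep over pixels in
    decreasing intensity order: when two catchment components merge, the one
    with the lower peak dies and its prominence is peak height minus the merge
    level.  The final surviving peak is measured against the image minimum, so
    a uniform image yields no maxima.  Ties are broken deterministically
    toward the smaller flat index; a connected plateau counts as one maximum
    reported at its (rounded) centroid.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"find_maxima requires a 2-D image, got ndim={img.ndim}")
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be > 0")
    nrow, ncol = img.shape
    flat = img.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))  # value desc, index asc

    parent = np.full(flat.size, -1, dtype=np.int64)  # -1 = not yet activated
    peak_of = np.empty(flat.size, dtype=np.int64)  # component root -> peak flat index

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    accepted: list[tuple[int, float]] = []  # (peak flat index, prominence)

    for p in order:
        p = int(p)
        r, c = divmod(p, ncol)
        roots = set()
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol:
                q = rr * ncol + cc
                if parent[q] != -1:
                    roots.add(find(q))
        parent[p] = p
        if not roots:
            peak_of[p] = p
            continue
        # dominant component: highest peak value, ties to smaller peak index
        def key(root: int) -> tuple[float, int]:
            pk = peak_of[root]
            return (flat[pk], -pk)

        dom = max(roots, key=key)
        for root in roots:
            if root != dom:
                pk = int(peak_of[root])
                prom = float(flat[pk] - flat[p])
                if prom > noise_tolerance:
                    accepted.append((pk, prom))
                parent[root] = dom
        parent[p] = dom

    # the last surviving component: prominence relative to the image minimum
    top = find(int(order[0]))
    pk = int(peak_of[top])
    prom = float(flat[pk] - flat.min())
    if prom > noise_tolerance:
        accepted.append((pk, prom))

    foci = []
    for pk, prom in accepted:
        pos, edge = _plateau_centroid(img, pk)
        foci.append(
            Focus(
                position=pos,
                peak_value=float(flat[pk]),
                prominence=prom,
                mean_intensity_3px=focus_mean_intensity(img, pos),
                frame=frame,
                edge=edge,
            )
        )
    foci.sort(key=lambda f: (-f.peak_value, f.position))
    return foci


def _plateau_centroid(img: np.ndarray, peak_flat: int) -> tuple[tuple[int, int], bool]:
    """Centroid (rounded) of the 8-connected equal-value plateau at a peak."""
    nrow, ncol = img.shape
    v = img.ravel()[peak_flat]
    start = (peak_flat // ncol, peak_flat % ncol)
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and (rr, cc) not in seen and img[rr, cc] == v:
                seen.add((rr, cc))
                stack.append((rr, cc))
    rows = np.array([p[0] for p in seen], dtype=float)
    cols = np.array([p[1] for p in seen], dtype=float)
    pos = (int(round(rows.mean())), int(round(cols.mean())))
    edge = pos[0] in (0, nrow - 1) or pos[1] in (0, ncol - 1)
    return pos, edge


def focus_mean_intensity(image, position) -> float:
    """Mean intensity within a 3-pixel-diameter circle centred on the focus.

    The circle is rasterized as the centre pixel plus its 4-neighbours; at an
    image border only in-bounds pixels contribute.
    """
    img = np.asarray(image, dtype=float)
    if hasattr(position, "position"):
        position = position.position
    r0, c0 = int(position[0]), int(position[1])
    vals = [
        img[r0 + dr, c0 + dc]
        for dr, dc in _CIRCLE3_OFFSETS
        if 0 <= r0 + dr < img.shape[0] and 0 <= c0 + dc < img.shape[1]
    ]
    if not vals:
        raise ValueError(f"focus position {position} lies outside the image")
    return float(np.mean(vals))


def foci_fraction(
    images,
    masks,
    noise_tolerance: float = 4000.0,
) -> pd.DataFrame:
    """Percentage of cells with >= 1 detected focus, per field of view.

    ``images`` and ``masks`` are matched sequences; each mask labels cells
    with positive integers (0 = background).  Foci falling outside every cell
    are counted as extracellular and excluded.
    """
    rows = []
    for i, (img, mask) in enumerate(zip(images, masks)):
        mask = np.asarray(mask)
        cells = set(int(v) for v in np.unique(mask) if v > 0)
        if not cells:
            raise ValueError(f"field {i}: mask contains no cells")
        foci = find_maxima(img, noise_tolerance, frame=None)
        with_focus = set()
        extracellular = 0
        for f in foci:
            lab = int(mask[f.position])
            if lab > 0:
                with_focus.add(lab)
            else:
                extracellular += 1
        rows.append(
            {
                "field": i,
                "n_cells": len(cells),
                "n_cells_with_foci": len(with_focus),
                "pct_cells_with_foci": 100.0 * len(with_focus) / len(cells),
                "n_foci": len(foci) - extracellular,
                "n_extracellular": extracellular,
            }
        )
    return pd.DataFrame(rows)


def cell_mean_intensity_trace(
    reporter_stack, mask, cell_id, frame_interval: float, label: int | None = None
) -> AggregationTrace:
    """Per-frame mean reporter intensity over one cell's mask pixels."""
    stack = np.asarray(reporter_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("reporter_stack must be (T, Y, X)")
    mask = np.asarray(mask)
    lab = int(label) if label is not None else int(cell_id)
    sel = mask == lab
    if not sel.any():
        raise ValueError(f"cell {cell_id!r}: no pixels with label {lab} in mask")
    series = stack[:, sel].mean(axis=1)
    return AggregationTrace(
        cell_id=str(cell_id), mean_intensity=series, frame_interval=frame_interval
    )


def fit_pre_dip_regression(
    agg_trace: AggregationTrace,
    dip_onset: int | None = None,
    min_span: float = 92.0,
) -> LinearFit:
    """OLS fit of reporter intensity vs time over the pre-dip window.

    The window is [0, dip_onset) frames when an onset is given, otherwise the
    full trace.  ``min_span`` (minutes, default 92 — a span below which the
    pre-dip baseline cannot be considered established) guards against fitting
    a line to a too-short segment.
    """
    end = agg_trace.n_frames if dip_onset is None else int(dip_onset)
    if not 2 <= end <= agg_trace.n_frames:
        raise ValueError(f"dip_onset {dip_onset} leaves no fit window")
    t = agg_trace.time[:end]
    y = agg_trace.mean_intensity[:end]
    span = float(t[-1] - t[0])
    if span < min_span:
        raise ValueError(
            f"pre-dip window spans {span:.1f} min, below the required {min_span:.1f} min"
        )
    res = stats.linregress(t, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        fit_window=(0, end),
    )


def rmsd(agg_trace: AggregationTrace, fit: LinearFit, window) -> float:
    """Root-mean-square deviation of intensity from the fitted line.

    ``window`` is an array/sequence of frame indices; deviations are measured
    minus predicted, squared, averaged over the window, and rooted.
    """
    idx = np.asarray(window, dtype=int)
    if idx.size == 0:
        raise ValueError("rmsd window is empty")
    if idx.min() < 0 or idx.max() >= agg_trace.n_frames:
        raise ValueError("rmsd window extends outside the trace")
    resid = agg_trace.mean_intensity[idx] - fit.predict(agg_trace.time[idx])
    return float(np.sqrt(np.mean(resid**2)))


def _window_label(minutes: float) -> str:
    hours = minutes / 60.0
    return f"after_{hours:g}h"


def rmsd_timecourse(
    agg_trace: AggregationTrace,
    fit: LinearFit,
    dip_onset: int,
    step: float = 30.0,
    horizon: float = 180.0,
) -> RmsdResult:
    """RMSD before the dip and over cumulative post-dip windows.

    *before* covers [0, onset); *after x h* covers frames with
    0 < t - t_onset <= x hours, in ``step``-minute increments up to
    ``horizon``.  Fold changes are after/before; ``max_fold`` is the largest
    fold within the horizon.  If the trace ends before the horizon the result
    is flagged partial and only complete-or-truncated windows that contain
    frames are reported.
    """
    if step <= 0 or horizon <= 0:
        raise ValueError("step and horizon must be > 0")
    onset = int(dip_onset)
    if not 0 < onset < agg_trace.n_frames:
        raise ValueError(f"dip_onset must lie inside the trace, got {onset}")
    before_idx = np.arange(0, onset)
    out = RmsdResult(
        rmsd_before=rmsd(agg_trace, fit, before_idx),
        pre_dip_span_min=float(agg_trace.time[onset - 1] - agg_trace.time[0]),
    )
    t = agg_trace.time
    t0 = t[onset]
    n_windows = int(round(horizon / step))
    for k in range(1, n_windows + 1):
        hi = k * step
        idx = np.nonzero((t - t0 > 0) & (t - t0 <= hi))[0]
        label = _window_label(hi)
        if idx.size == 0:
            out.partial = True
            break
        out.rmsd_after[label] = rmsd(agg_trace, fit, idx)
        if out.rmsd_before > 0:
            out.fold_changes[label] = out.rmsd_after[label] / out.rmsd_before
        if t[-1] - t0 < hi:  # truncated window; later ones would just repeat it
            out.partial = True
            break
    if out.fold_changes:
        out.max_fold = float(max(out.fold_changes.values()))
    return out


def expected_null_fold(times_pre: np.ndarray, times_window: np.ndarray) -> float:
    """Expected RMSD fold under the no-acceleration null.

    Even with no post-dip change, extrapolating an OLS line fitted on the
    pre-dip window inflates out-of-window residuals: at time t the prediction
    variance is sigma^2 * (1 + 1/n + (t - tbar)^2 / Sxx), while the in-window
    RMSD underestimates sigma by sqrt(1 - 2/n).  This returns the resulting
    expected after/before RMSD ratio, used both to calibrate the synthetic
    generator and as the proper null reference when testing whether a cohort's
    fold change is significantly above chance.
    """
    tp = np.asarray(times_pre, dtype=float)
    tw = np.asarray(times_window, dtype=float)
    n = tp.size
    if n < 3 or tw.size == 0:
        raise ValueError("need >= 3 pre-dip frames and a non-empty window")
    tbar = tp.mean()
    sxx = float(np.sum((tp - tbar) ** 2))
    num = float(np.mean(1.0 + 1.0 / n + (tw - tbar) ** 2 / sxx))
    den = 1.0 - 2.0 / n
    return float(np.sqrt(num / den))


def cohort_rmsd_report(
    dip_cells: list[tuple[AggregationTrace, int]],
    stable_cells: list[AggregationTrace] | None = None,
    step: float = 30.0,
    horizon: float = 180.0,
    min_span: float = 92.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell RMSD table and cohort summary.

    ``dip_cells`` are (aggregation trace, dip onset frame) pairs;
    ``stable_cells`` get a full-span fit and full-span RMSD for contrast.
    The summary reports mean/median max fold and the fraction of dip cells
    whose RMSD rose more than 3-fold (i.e. beyond three sigma of the pre-dip
    fluctuation).
    """
    rows = []
    folds = []
    for agg, onset in dip_cells:
        fit = fit_pre_dip_regression(agg, onset, min_span=min_span)
        res = rmsd_timecourse(agg, fit, onset, step=step, horizon=horizon)
        row = {
            "cell_id": agg.cell_id,
            "group": "dip",
            "dip_onset_frame": onset,
            "pre_dip_span_min": res.pre_dip_span_min,
            "rmsd_before": res.rmsd_before,
            "max_fold": res.max_fold,
            "partial": res.partial,
            "pearson_r": fit.pearson_r,
        }
        for lab, v in res.rmsd_after.items():
            row[f"rmsd_{lab}"] = v
        for lab, v in res.fold_changes.items():
            row[f"fold_{lab}"] = v
        rows.append(row)
        if np.isfinite(res.max_fold):
            folds.append(res.max_fold)
    for agg in stable_cells or []:
        fit = fit_pre_dip_regression(agg, None, min_span=min_span)
        full = np.arange(agg.n_frames)
        rows.append(
            {
                "cell_id": agg.cell_id,
                "group": "stable",
                "dip_onset_frame": None,
                "pre_dip_span_min": float(agg.time[-1]),
                "rmsd_before": rmsd(agg, fit, full),
                "max_fold": np.nan,
                "partial": False,
                "pearson_r": fit.pearson_r,
            }
        )
    table = pd.DataFrame(rows)
    folds_arr = np.asarray(folds, dtype=float)
    summary = {
        "n_dip_cells": len(dip_cells),
        "n_stable_cells": len(stable_cells or []),
        "mean_max_fold": float(folds_arr.mean()) if folds_arr.size else float("nan"),
        "median_max_fold": float(np.median(folds_arr)) if folds_arr.size else float("nan"),
        "frac_fold_gt3": float(np.mean(folds_arr > 3.0)) if folds_arr.size else float("nan"),
    }
    return table, summary
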