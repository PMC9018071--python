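"""Synthetic time-lapse generator with known ground truth.

Emulates the statistical structure the analysis assumes so that every
downstream stage can be exercised closed-loop: per-cell sensor-ratio traces
with a stable ~4 mM-equivalent baseline, stochastic deep dips (> 0.5 ratio
units for ~15 min) and shallow dips, irreversible shifts, unsynchronized
~35-min oscillations, rare single-frame acquisition errors (~1/70 frames,
one channel unusually intense), reporter-intensity traces rising linearly
(Pearson r ~ 0.99) with an optional post-dip acceleration calibrated to a
target maximum RMSD fold change, and rendered two-channel image stacks with
label masks and planted foci.

Depletion events are injected as rectangular drops: the drop completes
within one frame (the imaging regime cannot resolve the few-minute descent),
stays at the nadir for the requested number of frames, and recovers in a
single step (or never, for a shift).  Truth labels follow directly from the
injected (depth, duration, recovered) parameters through the same
definitional predicate the classifier uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .classification import label_event
from .config import SyntheticConfig
from .foci import expected_null_fold
from .traces import AggregationTrace, ChannelTraces, RatioTrace

__all__ = [
    "TrueEvent",
    "CellTruth",
    "SyntheticGroundTruth",
    "Cohort",
    "ImageStackData",
    "gen_stable_trace",
    "gen_dip_trace",
    "gen_oscillating_trace",
    "gen_channel_traces",
    "inject_frame_errors",
    "gen_aggregation_trace",
    "gen_cell_image_stack",
    "gen_cohort",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth depletion event as injected."""

    onset: int
    depth: float
    duration_frames: int
    recovered: bool


@dataclass
class CellTruth:
    cell_id: str
    label: str  # stable | dip | shallow_dip | shift | oscillating
    events: list[TrueEvent] = field(default_factory=list)
    period_min: float | None = None
    agg_slope: float | None = None
    agg_intercept: float | None = None
    agg_sigma: float | None = None
    dip_onset: int | None = None
    target_max_fold: float | None = None

    @property
    def expected_classification(self) -> str:
        """Label the threshold classifier should assign to this cell."""
        return "stable" if self.label == "oscillating" else self.label


@dataclass
class SyntheticGroundTruth:
    cells: list[CellTruth] = field(default_factory=list)
    # cell_id -> channel name -> corrupted frame indices
    corrupted_frames: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def by_id(self) -> dict[str, CellTruth]:
        return {c.cell_id: c for c in self.cells}

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": [asdict(c) for c in self.cells],
                "corrupted_frames": self.corrupted_frames,
            },
            sort_keys=True,
            indent=2,
        )


def _stable_signal(config: SyntheticConfig) -> np.ndarray:
    return np.full(config.n_frames, config.baseline_ratio, dtype=float)


def _add_noise(signal: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.ratio_noise_sd == 0:
        return signal.copy()
    return signal + rng.normal(0.0, config.ratio_noise_sd, size=signal.size)


def gen_stable_trace(
    config: SyntheticConfig, seed, cell_id: str = "cell"
) -> tuple[RatioTrace, CellTruth]:
    """Flat baseline plus i.i.d. Gaussian noise; no injected events."""
    rng = _rng(seed)
    sig = _stable_signal(config)
    trace = RatioTrace(
        cell_id=cell_id, ratio=_add_noise(sig, config, rng), frame_interval=config.frame_interval
    )
    return trace, CellTruth(cell_id=cell_id, label="stable")


def _dip_signal(
    config: SyntheticConfig,
    events: list[TrueEvent],
) -> np.ndarray:
    sig = _stable_signal(config)
    for ev in events:
        if ev.recovered:
            sig[ev.onset : ev.onset + ev.duration_frames] -= ev.depth
        else:
            sig[ev.onset :] -= ev.depth
    return sig


def gen_dip_trace(
    config: SyntheticConfig,
    seed,
    depth: float,
    duration_frames: int,
    recover: bool = True,
    onset: int | None = None,
    cell_id: str = "cell",
) -> tuple[RatioTrace, CellTruth]:
    """Stable trace with one injected depletion event.

    A recovered event drops by ``depth`` for exactly ``duration_frames``
    frames then returns to baseline; an unrecovered event (``recover=False``)
    persists to the end of the trace (an ATP shift when deep enough).  The
    truth label follows the classifier's definitional predicate applied to
    the injected parameters.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if duration_frames < 1:
        raise ValueError("duration_frames must be >= 1")
    rng = _rng(seed)
    n = config.n_frames
    min_onset = 6  # room for a pre-event baseline window
    if recover:
        max_onset = n - duration_frames - 1  # recovery frame must exist
    else:
        max_onset = n - 2
    if max_onset < min_onset:
        raise ValueError(
            f"event of {duration_frames} frames does not fit in a {n}-frame trace"
        )
    if onset is None:
        onset = int(rng.integers(min_onset, max_onset + 1))
    if not min_onset <= onset <= max_onset:
        raise ValueError(f"onset must lie in [{min_onset}, {max_onset}], got {onset}")
    dur = duration_frames if recover else n - onset
    ev = TrueEvent(onset=onset, depth=float(depth), duration_frames=dur, recovered=recover)
    sig = _dip_signal(config, [ev])
    trace = RatioTrace(
        cell_id=cell_id, ratio=_add_noise(sig, config, rng), frame_interval=config.frame_interval
    )
    lab = label_event(ev.depth, ev.duration_frames, ev.recovered)
    truth = CellTruth(cell_id=cell_id, label=lab if lab != "none" else "stable", events=[ev])
    return trace, truth


def gen_oscillating_trace(
    config: SyntheticConfig, seed, cell_id: str = "cell"
) -> tuple[RatioTrace, CellTruth]:
    """Baseline plus a sinusoid with uniformly random phase plus noise.

    Phases are independent across cells: the oscillation is unsynchronized in
    the population.
    """
    if config.osc_period <= 2 * config.frame_interval:
        raise ValueError(
            f"osc_period ({config.osc_period} min) must exceed twice the frame "
            f"interval ({config.frame_interval} min)"
        )
    rng = _rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(config.n_frames) * config.frame_interval
    sig = _stable_signal(config) + config.osc_amplitude * np.sin(
        2.0 * np.pi * t / config.osc_period + phase
    )
    trace = RatioTrace(
        cell_id=cell_id, ratio=_add_noise(sig, config, rng), frame_interval=config.frame_interval
    )
    return trace, CellTruth(cell_id=cell_id, label="oscillating", period_min=config.osc_period)


def gen_channel_traces(
    config: SyntheticConfig, seed, true_ratio: np.ndarray, cell_id: str = "cell"
) -> ChannelTraces:
    """Two excitation-channel traces whose ratio carries the given signal.

    Each channel receives independent multiplicative Gaussian noise scaled so
    the resulting ratio noise near baseline approximates ``ratio_noise_sd``.
    """
    rng = _rng(seed)
    frac_sd = config.ratio_noise_sd / (config.baseline_ratio * np.sqrt(2.0))
    n = true_ratio.size
    base = config.channel_base_490
    ex490 = base * (1.0 + rng.normal(0.0, frac_sd, n))
    ex410 = np.asarray(true_ratio) * base * (1.0 + rng.normal(0.0, frac_sd, n))
    eps = 1e-6 * base
    return ChannelTraces(
        cell_id=cell_id,
        ex410=np.clip(ex410, eps, None),
        ex490=np.clip(ex490, eps, None),
        frame_interval=config.frame_interval,
    )


def _robust_channel_sd(x: np.ndarray) -> float:
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def inject_frame_errors(
    channels: ChannelTraces,
    rate: float,
    magnitude: float,
    seed,
    channel_sd: tuple[float, float] | None = None,
) -> tuple[ChannelTraces, dict[str, list[int]]]:
    """Corrupt random frames so exactly one channel is anomalously intense.

    At each frame independently with probability ``rate``, one channel
    (chosen uniformly) receives a positive offset of ``magnitude`` channel
    noise SDs, mimicking a mis-exposed acquisition.  Returns the corrupted
    traces and the truth indices per channel.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0 (in channel noise SDs)")
    rng = _rng(seed)
    ex410 = channels.ex410.copy()
    ex490 = channels.ex490.copy()
    if channel_sd is None:
        channel_sd = (_robust_channel_sd(ex410), _robust_channel_sd(ex490))
    truth: dict[str, list[int]] = {"ex410": [], "ex490": []}
    hit = rng.random(channels.n_frames) < rate
    which = rng.integers(0, 2, size=channels.n_frames)
    for k in np.nonzero(hit)[0]:
        if which[k] == 0:
            ex410[k] += magnitude * channel_sd[0]
            truth["ex410"].append(int(k))
        else:
            ex490[k] += magnitude * channel_sd[1]
            truth["ex490"].append(int(k))
    out = ChannelTraces(
        cell_id=channels.cell_id,
        ex410=ex410,
        ex490=ex490,
        frame_interval=channels.frame_interval,
    )
    return out, truth


def gen_aggregation_trace(
    config: SyntheticConfig,
    seed,
    dip_onset: int | None = None,
    cell_id: str = "cell",
) -> tuple[AggregationTrace, CellTruth]:
    """Linearly rising reporter-intensity trace, optionally accelerating after a dip.

    Noise is calibrated so a full-span linear fit yields Pearson r close to
    ``agg_corr_target``.  When ``dip_onset`` is given, a stochastic ramp is
    added after the onset, scaled per cell by a unit-mean lognormal factor and
    calibrated — accounting for the extrapolation inflation of the null RMSD
    fold — so the expected maximum RMSD fold within ``post_dip_horizon``
    equals ``post_dip_fold``.
    """
    if config.post_dip_horizon <= 0:
        raise ValueError("post_dip_horizon must be > 0")
    rng = _rng(seed)
    n = config.n_frames
    if dip_onset is not None and not 0 < dip_onset < n:
        raise ValueError(f"dip_onset must lie in (0, {n}), got {dip_onset}")
    t = np.arange(n) * config.frame_interval
    r = config.agg_corr_target
    sigma = config.agg_slope * float(np.std(t)) * np.sqrt(1.0 / r**2 - 1.0)
    y = config.agg_intercept + config.agg_slope * t + rng.normal(0.0, sigma, n)
    truth = CellTruth(
        cell_id=cell_id,
        label="stable",
        agg_slope=config.agg_slope,
        agg_intercept=config.agg_intercept,
        agg_sigma=sigma,
        dip_onset=dip_onset,
    )
    if dip_onset is not None and config.post_dip_fold > 1.0:
        t0 = t[dip_onset]
        h = config.post_dip_horizon
        in_h = (t - t0 > 0) & (t - t0 <= h)
        if in_h.any():
            nu = expected_null_fold(t[:dip_onset], t[in_h])
            s = config.post_dip_fold_spread
            cell_factor = float(rng.lognormal(mean=-0.5 * s**2, sigma=s)) if s > 0 else 1.0
            delta = sigma * np.sqrt(max(config.post_dip_fold**2 - nu**2, 0.0)) * cell_factor
            post = t > t0
            y[post] += delta * np.sqrt(3.0) * (t[post] - t0) / h
            truth.target_max_fold = config.post_dip_fold
    agg = AggregationTrace(
        cell_id=cell_id, mean_intensity=y, frame_interval=config.frame_interval
    )
    return agg, truth


@dataclass
class ImageStackData:
    """Rendered synthetic field of view with ground truth."""

    queen: np.ndarray  # (T, 2, Y, X): channels [ex410, ex490]
    reporter: np.ndarray  # (T, Y, X) or (T, Z, Y, X) when n_z > 1
    mask: np.ndarray  # (Y, X) integer labels, 0 = background
    centers: list[tuple[int, int]]
    ratios: np.ndarray  # (n_cells, T) per-cell ratio rendered
    foci: dict[int, list[tuple[int, int]]]  # cell label -> planted focus positions


def gen_cell_image_stack(
    config: SyntheticConfig,
    seed,
    n_cells: int | None = None,
    ratios: np.ndarray | None = None,
    foci_cells: dict[int, int] | None = None,
    n_frames: int | None = None,
    n_z: int = 1,
    max_tries: int = 2000,
) -> ImageStackData:
    """Render non-overlapping disk cells into a two-channel sensor stack.

    Per-cell mean ratio of the rendered channels reproduces the requested
    (or baseline) ratio trace exactly in the noiseless case.  The reporter
    channel renders a cytoplasmic background plus Gaussian foci of amplitude
    ``focus_amplitude`` (sigma ``psf_sigma``) at planted positions; with
    ``n_z`` > 1 the foci live in the central slice so that a maximum
    projection recovers the single-plane image.
    """
    rng = _rng(seed)
    n_cells = int(n_cells if n_cells is not None else config.n_cells)
    T = int(n_frames if n_frames is not None else config.n_frames)
    size = config.image_size
    rad = config.cell_radius

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells of radius {rad} "
                f"in a {size}x{size} image after {max_tries} tries"
            )
        r0 = int(rng.integers(rad + 1, size - rad - 1))
        c0 = int(rng.integers(rad + 1, size - rad - 1))
        if all((r0 - r) ** 2 + (c0 - c) ** 2 >= (2 * rad + 2) ** 2 for r, c in centers):
            centers.append((r0, c0))

    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=np.int32)
    for i, (r0, c0) in enumerate(centers, start=1):
        mask[(yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2] = i

    if ratios is None:
        ratios = np.full((n_cells, T), config.baseline_ratio, dtype=float)
    else:
        ratios = np.asarray(ratios, dtype=float)
        if ratios.shape != (n_cells, T):
            raise ValueError(f"ratios must have shape ({n_cells}, {T})")

    base = config.channel_base_490
    queen = np.full((T, 2, size, size), config.image_background, dtype=float)
    for i in range(n_cells):
        sel = mask == i + 1
        for tfr in range(T):
            queen[tfr, 0][sel] = ratios[i, tfr] * base
            queen[tfr, 1][sel] = base

    if foci_cells is None:
        foci_cells = {}
    foci: dict[int, list[tuple[int, int]]] = {}
    plane = np.full((size, size), config.image_background, dtype=float)
    plane[mask > 0] = config.cell_background
    for lab, count in foci_cells.items():
        r0, c0 = centers[lab - 1]
        positions = []
        for _ in range(count):
            ang = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, rad / 2.0)
            positions.append((int(round(r0 + rr * np.sin(ang))), int(round(c0 + rr * np.cos(ang)))))
        foci[lab] = positions
        for fr, fc in positions:
            plane += config.focus_amplitude * np.exp(
                -((yy - fr) ** 2 + (xx - fc) ** 2) / (2.0 * config.psf_sigma**2)
            )
    if n_z > 1:
        bg = np.full((size, size), config.image_background, dtype=float)
        bg[mask > 0] = config.cell_background
        reporter = np.stack(
            [np.tile(bg, (n_z, 1, 1)) for _ in range(T)]
        )  # (T, Z, Y, X)
        reporter[:, n_z // 2] = plane
    else:
        reporter = np.tile(plane, (T, 1, 1))

    if config.pixel_poisson:
        queen = rng.poisson(np.clip(queen, 0, None)).astype(float)
        reporter = rng.poisson(np.clip(reporter, 0, None)).astype(float)
    if config.pixel_noise_sd > 0:
        queen = queen + rng.normal(0, config.pixel_noise_sd, queen.shape)
        reporter = reporter + rng.normal(0, config.pixel_noise_sd, reporter.shape)

    return ImageStackData(
        queen=queen, reporter=reporter, mask=mask, centers=centers, ratios=ratios, foci=foci
    )


@dataclass
class Cohort:
    """Generated cohort: traces plus paired aggregation traces and truth."""

    config: SyntheticConfig
    ratio_traces: list[RatioTrace]
    agg_traces: list[AggregationTrace]
    truth: SyntheticGroundTruth
    channel_traces: list[ChannelTraces] | None = None


def _draw_dip_events(
    config: SyntheticConfig, rng: np.random.Generator, deep: bool
) -> list[TrueEvent]:
    """Non-overlapping recovered dips; the count follows the per-cell dip rate."""
    n = config.n_frames
    span_h = (n - 1) * config.frame_interval / 60.0
    n_events = max(1, int(rng.poisson(config.dip_rate * span_h)))
    lo, hi = config.dip_depth_range if deep else config.shallow_depth_range
    min_predip = max(config.n_frames // 6, 24)
    horizon_frames = int(np.ceil(config.post_dip_horizon / config.frame_interval))
    events: list[TrueEvent] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(n_events):
        dur = int(np.clip(config.dip_duration_frames + rng.integers(-1, 2), 3, None))
        # leave room for the full post-dip RMSD horizon when the trace allows it
        max_onset = n - horizon_frames - 2
        if max_onset <= min_predip:
            max_onset = n - dur - 2
        for _ in range(50):
            onset = int(rng.integers(min_predip, max_onset + 1))
            if all(onset + dur + 6 < a or onset > b + 6 for a, b in occupied):
                occupied.append((onset, onset + dur))
                events.append(
                    TrueEvent(onset=onset, depth=float(rng.uniform(lo, hi)),
                              duration_frames=dur, recovered=True)
                )
                break
    events.sort(key=lambda e: e.onset)
    return events


def gen_cohort(
    config: SyntheticConfig,
    seed=None,
    with_channels: bool = False,
    frame_errors: bool | None = None,
) -> Cohort:
    """Generate a mixed cohort of cells per the configured class proportions.

    Each cell draws its class (stable / dip / shallow dip / shift /
    oscillating) independently from ``config.mix``.  Every cell receives a
    paired aggregation trace; dip cells accelerate after their first dip
    onset.  With ``with_channels`` the per-cell two-channel traces are also
    generated (from the noiseless ratio signal plus channel noise) and
    acquisition errors are injected at ``frame_error_rate`` unless
    ``frame_errors=False``.
    """
    rng = _rng(config.seed if seed is None else seed)
    if frame_errors is None:
        frame_errors = with_channels
    classes = ("stable", "dip", "shallow_dip", "shift", "oscillating")
    p = np.asarray(config.mix.as_tuple())
    n = config.n_frames
    truth = SyntheticGroundTruth()
    ratio_traces: list[RatioTrace] = []
    agg_traces: list[AggregationTrace] = []
    channel_traces: list[ChannelTraces] | None = [] if with_channels else None

    for i in range(config.n_cells):
        cid = f"cell{i:04d}"
        cls = classes[int(rng.choice(len(classes), p=p))]
        events: list[TrueEvent] = []
        period = None
        if cls == "stable":
            sig = _stable_signal(config)
        elif cls in ("dip", "shallow_dip"):
            events = _draw_dip_events(config, rng, deep=(cls == "dip"))
            sig = _dip_signal(config, events)
        elif cls == "shift":
            onset = int(rng.integers(max(n // 6, 24), n - 8))
            depth = float(rng.uniform(config.shallow_depth_range[0], config.dip_depth_range[1]))
            events = [TrueEvent(onset=onset, depth=depth, duration_frames=n - onset,
                                recovered=False)]
            sig = _dip_signal(config, events)
        else:  # oscillating
            phase = rng.uniform(0.0, 2.0 * np.pi)
            t = np.arange(n) * config.frame_interval
            sig = _stable_signal(config) + config.osc_amplitude * np.sin(
                2.0 * np.pi * t / config.osc_period + phase
            )
            period = config.osc_period

        trace = RatioTrace(
            cell_id=cid, ratio=_add_noise(sig, config, rng),
            frame_interval=config.frame_interval,
        )
        ratio_traces.append(trace)

        dip_onset = events[0].onset if cls == "dip" else None
        agg, agg_truth = gen_aggregation_trace(config, rng, dip_onset=dip_onset, cell_id=cid)
        agg_traces.append(agg)

        cell_truth = CellTruth(
            cell_id=cid,
            label=cls,
            events=events,
            period_min=period,
            agg_slope=agg_truth.agg_slope,
            agg_intercept=agg_truth.agg_intercept,
            agg_sigma=agg_truth.agg_sigma,
            dip_onset=dip_onset,
            target_max_fold=agg_truth.target_max_fold,
        )
        truth.cells.append(cell_truth)

        if with_channels:
            ch = gen_channel_traces(config, rng, sig, cell_id=cid)
            if frame_errors and config.frame_error_rate > 0:
                ch, corrupted = inject_frame_errors(
                    ch, config.frame_error_rate, config.frame_error_magnitude, rng
                )
                truth.corrupted_frames[cid] = corrupted
            channel_traces.append(ch)

    return Cohort(
        config=config,
        ratio_traces=ratio_traces,
        agg_traces=agg_traces,
        truth=truth,
        channel_traces=channel_traces,
    )
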