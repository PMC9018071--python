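"""Generator correctness: determinism, truth consistency, calibrated statistics."""

import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats

from queenflux import (
    SyntheticConfig,
    compute_ratio_trace,
    extract_cell_trace,
    gen_aggregation_trace,
    gen_cell_image_stack,
    gen_cohort,
    gen_dip_trace,
    gen_oscillating_trace,
    gen_stable_trace,
    inject_frame_errors,
)
from queenflux.classification import label_event
from queenflux.config import CohortMix
from queenflux.io import write_traces_csv
from queenflux.synthetic import gen_channel_traces


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_frames", 2),
        ("frame_interval", 0.0),
        ("dip_depth_range", (0.1, 0.4)),  # cannot generate deep dips
        ("osc_period", 7.0),  # sub-Nyquist at 4-min frames
        ("frame_error_rate", 1.5),
        ("image_size", 20),  # < 4 x cell_radius
    ],
)
def test_invalid_config_rejected_naming_field(field, value):
    with pytest.raises(ValidationError) as exc:
        SyntheticConfig(**{field: value})
    msg = str(exc.value)
    assert field in msg or field.split("_")[0] in msg


def test_stable_trace_zero_noise_is_constant_baseline():
    cfg = SyntheticConfig(ratio_noise_sd=0.0)
    trace, truth = gen_stable_trace(cfg, seed=0)
    assert truth.label == "stable"
    assert np.all(trace.ratio == cfg.baseline_ratio)


def test_same_seed_gives_identical_traces(config):
    a, _ = gen_stable_trace(config, seed=99)
    b, _ = gen_stable_trace(config, seed=99)
    np.testing.assert_array_equal(a.ratio, b.ratio)


def test_stable_noise_sd_within_chisquare_interval():
    # sample SD of 300 i.i.d. N(0, 0.05) draws falls in [0.04, 0.06] for
    # essentially every seed (chi-square 99.9% interval is tighter)
    cfg = SyntheticConfig(n_frames=300)
    hits = 0
    for seed in range(100):
        trace, _ = gen_stable_trace(cfg, seed)
        hits += 0.04 <= trace.ratio.std(ddof=1) <= 0.06
    assert hits >= 95


@pytest.mark.parametrize(
    "depth, duration, recover, expected",
    [
        (0.6, 4, True, "dip"),
        (0.4, 4, False, "shift"),
        (0.4, 4, True, "shallow_dip"),
        (0.6, 2, True, "shallow_dip"),  # deep but too short to span > 2 frames
    ],
)
def test_dip_trace_truth_label(depth, duration, recover, expected):
    cfg = SyntheticConfig(ratio_noise_sd=0.0)
    trace, truth = gen_dip_trace(cfg, seed=1, depth=depth, duration_frames=duration, recover=recover)
    assert truth.label == expected
    ev = truth.events[0]
    assert 0 <= ev.onset < cfg.n_frames
    # the injected drop is exactly rectangular
    nadir = trace.ratio.min()
    assert nadir == pytest.approx(cfg.baseline_ratio - depth)


def test_dip_event_must_fit_inside_trace():
    cfg = SyntheticConfig(n_frames=30)
    with pytest.raises(ValueError, match="fit"):
        gen_dip_trace(cfg, seed=0, depth=0.6, duration_frames=40)


def test_oscillating_zero_amplitude_matches_stable():
    cfg = SyntheticConfig(osc_amplitude=0.0, ratio_noise_sd=0.0)
    trace, truth = gen_oscillating_trace(cfg, seed=2)
    assert np.all(trace.ratio == cfg.baseline_ratio)
    assert truth.period_min == cfg.osc_period


def test_oscillating_dominant_fft_period():
    cfg = SyntheticConfig(n_frames=300, ratio_noise_sd=0.0)
    trace, _ = gen_oscillating_trace(cfg, seed=3)
    x = trace.ratio - trace.ratio.mean()
    freqs = np.fft.rfftfreq(x.size, d=cfg.frame_interval)
    k = np.argmax(np.abs(np.fft.rfft(x))[1:]) + 1
    # dominant frequency within one bin of 1/35 per minute
    assert abs(freqs[k] - 1.0 / cfg.osc_period) <= freqs[1]


def test_oscillating_phases_uniform_across_seeds():
    cfg = SyntheticConfig(n_frames=200, ratio_noise_sd=0.0)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    w = 2 * np.pi / cfg.osc_period
    phases = []
    for seed in range(100):
        trace, _ = gen_oscillating_trace(cfg, seed)
        x = trace.ratio - cfg.baseline_ratio
        phases.append(np.arctan2(np.sum(x * np.cos(w * t)), np.sum(x * np.sin(w * t))))
    # circular resultant of n uniform phases: R^2 ~ Exp(mean 1/n); Rayleigh test
    n = len(phases)
    r2 = np.mean(np.cos(phases)) ** 2 + np.mean(np.sin(phases)) ** 2
    assert n * r2 < 7.0  # p ~ exp(-7) under uniformity


def test_inject_frame_errors_rate_zero_is_identity(config, rng):
    ch = gen_channel_traces(config, rng, np.full(config.n_frames, 1.0))
    out, truth = inject_frame_errors(ch, rate=0.0, magnitude=8.0, seed=1)
    np.testing.assert_array_equal(out.ex410, ch.ex410)
    np.testing.assert_array_equal(out.ex490, ch.ex490)
    assert truth == {"ex410": [], "ex490": []}


def test_inject_frame_errors_binomial_mean_count():
    cfg = SyntheticConfig(n_frames=700)
    counts = []
    for seed in range(100):
        ch = gen_channel_traces(cfg, seed, np.full(700, 1.0))
        _, truth = inject_frame_errors(ch, rate=1 / 70, magnitude=8.0, seed=seed + 1000)
        counts.append(len(truth["ex410"]) + len(truth["ex490"]))
    # Binomial(700, 1/70): mean 10, SE of the mean over 100 runs ~ 0.31
    assert abs(np.mean(counts) - 10.0) < 1.0


def test_inject_magnitude_zero_records_truth_but_leaves_traces(config, rng):
    ch = gen_channel_traces(config, rng, np.full(config.n_frames, 1.0))
    out, truth = inject_frame_errors(ch, rate=0.5, magnitude=0.0, seed=4)
    assert len(truth["ex410"]) + len(truth["ex490"]) > 0
    np.testing.assert_array_equal(out.ex410, ch.ex410)


def test_aggregation_near_noiseless_is_linear():
    cfg = SyntheticConfig(agg_corr_target=1 - 1e-12)
    agg, truth = gen_aggregation_trace(cfg, seed=0)
    r = np.corrcoef(agg.time, agg.mean_intensity)[0, 1]
    assert r > 0.999999
    assert truth.agg_slope == cfg.agg_slope


def test_aggregation_calibrated_noise_mean_correlation():
    cfg = SyntheticConfig()
    rng = np.random.default_rng(5)
    rs = []
    for _ in range(20):
        agg, _ = gen_aggregation_trace(cfg, rng)
        rs.append(np.corrcoef(agg.time, agg.mean_intensity)[0, 1])
    assert np.mean(rs) >= 0.98


def test_cohort_all_stable():
    cfg = SyntheticConfig(n_cells=25, mix=CohortMix(stable=1.0, dip=0, shallow_dip=0, shift=0))
    co = gen_cohort(cfg, seed=0)
    assert all(c.label == "stable" for c in co.truth.cells)


def test_cohort_truth_fraction_within_binomial_ci():
    mix = CohortMix(stable=0.65, dip=0.25, shallow_dip=0.0, shift=0.10)
    cfg = SyntheticConfig(n_cells=200, mix=mix)
    co = gen_cohort(cfg, seed=8)
    n_event = sum(c.label in ("dip", "shift") for c in co.truth.cells)
    lo, hi = stats.binom.interval(0.999, 200, 0.35)
    assert lo <= n_event <= hi


def test_cohort_truth_labels_match_definitional_predicate():
    cfg = SyntheticConfig(n_cells=60, ratio_noise_sd=0.0)
    co = gen_cohort(cfg, seed=9)
    for cell in co.truth.cells:
        kinds = [label_event(e.depth, e.duration_frames, e.recovered) for e in cell.events]
        if "dip" in kinds:
            assert cell.label == "dip"
        elif "shift" in kinds:
            assert cell.label == "shift"
        elif "shallow_dip" in kinds:
            assert cell.label == "shallow_dip"
        else:
            assert cell.label in ("stable", "oscillating")


def test_cohort_csv_byte_identical_across_runs(tmp_path):
    cfg = SyntheticConfig(n_cells=20)
    paths = []
    for run in range(2):
        co = gen_cohort(cfg, seed=31)
        p = tmp_path / f"traces_{run}.csv"
        write_traces_csv(co.ratio_traces, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_image_stack_ratio_roundtrip_noiseless(small_config):
    ratios = np.full((1, 5), 1.7)
    data = gen_cell_image_stack(small_config, seed=0, n_cells=1, ratios=ratios)
    ch = extract_cell_trace(data.queen, data.mask, 1, small_config.frame_interval)
    trace = compute_ratio_trace(ch)
    np.testing.assert_allclose(trace.ratio, 1.7, atol=1e-9)


def test_image_stack_gain_invariance(small_config):
    data = gen_cell_image_stack(small_config, seed=1, n_cells=2)
    scaled = data.queen * 3.5
    a = compute_ratio_trace(extract_cell_trace(data.queen, data.mask, 1, 4.0))
    b = compute_ratio_trace(extract_cell_trace(scaled, data.mask, 1, 4.0))
    np.testing.assert_allclose(a.ratio, b.ratio, rtol=1e-12)


def test_image_stack_planted_foci_recovered(small_config):
    from queenflux import find_maxima

    data = gen_cell_image_stack(small_config, seed=2, n_cells=3, foci_cells={1: 1, 2: 1, 3: 1})
    foci = find_maxima(data.reporter[0], noise_tolerance=4000)
    assert len(foci) == 3
    planted = [pos for positions in data.foci.values() for pos in positions]
    for f in foci:
        assert min(abs(f.position[0] - r) + abs(f.position[1] - c) for r, c in planted) <= 1


def test_image_stack_empty_mask_region_refused(small_config):
    data = gen_cell_image_stack(small_config, seed=3, n_cells=1)
    with pytest.raises(ValueError, match="label"):
        extract_cell_trace(data.queen, data.mask, 99, 4.0)


def test_too_many_cells_to_place_raises():
    cfg = SyntheticConfig(image_size=64, cell_radius=12)
    with pytest.raises(ValueError, match="place"):
        gen_cell_image_stack(cfg, seed=0, n_cells=10, max_tries=50)
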