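"""Prominence-based foci detection and the pre-dip-regression RMSD statistic."""

import numpy as np
import pytest
from scipy import stats

from oracle_utils import prominence_maxima, rmsd_direct

from queenflux import (
    AggregationTrace,
    SyntheticConfig,
    cell_mean_intensity_trace,
    cohort_rmsd_report,
    expected_null_fold,
    find_maxima,
    fit_pre_dip_regression,
    foci_fraction,
    focus_mean_intensity,
    gen_aggregation_trace,
    rmsd,
    rmsd_timecourse,
)
from queenflux.foci import LinearFit


def _gaussian_spot(img, r0, c0, amp, sigma=1.5):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img += amp * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2))
    return img


class TestFindMaxima:
    def test_uniform_image_has_no_foci(self):
        assert find_maxima(np.full((20, 20), 5000.0), 4000) == []

    def test_single_spot_above_tolerance(self):
        img = _gaussian_spot(np.zeros((32, 32)), 15, 17, 10000)
        foci = find_maxima(img, 4000)
        assert len(foci) == 1
        assert foci[0].position == (15, 17)

    def test_two_spot_tolerance_splits(self):
        img = np.zeros((40, 40))
        _gaussian_spot(img, 10, 10, 10000)
        _gaussian_spot(img, 30, 30, 5000)
        assert len(find_maxima(img, 4000)) == 2
        assert len(find_maxima(img, 6000)) == 1

    def test_matches_bruteforce_prominence_oracle(self):
        rng = np.random.default_rng(0)
        levels = np.arange(0, 20000, 400)
        for trial in range(200):
            img = rng.choice(levels, size=(32, 32))
            tol = float(rng.choice([800, 2000, 5000]))
            got = sorted((f.position, f.peak_value, f.prominence) for f in find_maxima(img, tol))
            assert got == prominence_maxima(img, tol), f"trial {trial}"

    def test_invariant_under_constant_offset(self, rng):
        img = rng.uniform(0, 10000, (24, 24))
        a = [(f.position, f.prominence) for f in find_maxima(img, 3000)]
        b = [(f.position, f.prominence) for f in find_maxima(img + 1234.5, 3000)]
        assert a == b

    def test_translation_equivariance(self, rng):
        img = np.zeros((40, 40))
        _gaussian_spot(img, 12, 14, 9000)
        shifted = np.roll(img, (5, -3), axis=(0, 1))
        a = find_maxima(img, 4000)[0].position
        b = find_maxima(shifted, 4000)[0].position
        assert (a[0] + 5, a[1] - 3) == b

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            find_maxima(np.zeros((3, 4, 5)), 100)


class TestFocusMeanIntensity:
    def test_constant_image(self):
        assert focus_mean_intensity(np.full((9, 9), 7.0), (4, 4)) == 7.0

    def test_center_plus_four_neighbors(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            img[4 + dr, 4 + dc] = 50
        assert focus_mean_intensity(img, (4, 4)) == pytest.approx((100 + 4 * 50) / 5)

    def test_corner_uses_in_bounds_subset(self):
        img = np.zeros((9, 9))
        img[0, 0] = 90
        img[0, 1] = 30
        img[1, 0] = 30
        assert focus_mean_intensity(img, (0, 0)) == pytest.approx((90 + 30 + 30) / 3)


class TestFociFraction:
    def _field(self, n_cells, foci_in, size=96, rad=6, seed=0):
        cfg = SyntheticConfig(image_size=size, cell_radius=rad, n_frames=3)
        from queenflux import gen_cell_image_stack

        data = gen_cell_image_stack(
            cfg, seed=seed, n_cells=n_cells, n_frames=1,
            foci_cells={lab: 1 for lab in range(1, foci_in + 1)},
        )
        return data.reporter[0], data.mask

    def test_no_foci_planted_gives_zero(self):
        img, mask = self._field(5, 0)
        out = foci_fraction([img], [mask])
        assert out["pct_cells_with_foci"].iloc[0] == 0.0

    def test_seven_of_ten_cells(self):
        img, mask = self._field(10, 7, size=128)
        out = foci_fraction([img], [mask])
        assert out["pct_cells_with_foci"].iloc[0] == pytest.approx(70.0)

    def test_pooled_mean_is_cell_weighted_mean(self):
        f1 = self._field(4, 2, seed=1)
        f2 = self._field(8, 2, seed=2, size=128)
        out = foci_fraction([f1[0], f2[0]], [f1[1], f2[1]])
        pooled = 100.0 * out["n_cells_with_foci"].sum() / out["n_cells"].sum()
        weighted = (out["pct_cells_with_foci"] * out["n_cells"]).sum() / out["n_cells"].sum()
        assert pooled == pytest.approx(weighted)


class TestCellMeanIntensityTrace:
    def test_uniform_stack_gives_constant(self):
        mask = np.zeros((8, 8), int)
        mask[2:5, 2:5] = 1
        agg = cell_mean_intensity_trace(np.full((4, 8, 8), 3.5), mask, 1, 4.0)
        np.testing.assert_array_equal(agg.mean_intensity, 3.5)

    def test_single_pixel_mask(self, rng):
        stack = rng.uniform(0, 10, (5, 8, 8))
        mask = np.zeros((8, 8), int)
        mask[4, 4] = 1
        agg = cell_mean_intensity_trace(stack, mask, 1, 4.0)
        np.testing.assert_array_equal(agg.mean_intensity, stack[:, 4, 4])

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            cell_mean_intensity_trace(np.zeros((2, 8, 8)), np.zeros((8, 8), int), 1, 4.0)


class TestPreDipRegression:
    def test_exact_line(self):
        t = np.arange(60) * 4.0
        agg = AggregationTrace("c", 2.0 * t + 5.0, 4.0)
        fit = fit_pre_dip_regression(agg)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_decreasing_line_r_minus_one(self):
        t = np.arange(60) * 4.0
        agg = AggregationTrace("c", -1.5 * t + 400.0, 4.0)
        assert fit_pre_dip_regression(agg).pearson_r == pytest.approx(-1.0)

    def test_short_window_refused_with_span(self):
        agg = AggregationTrace("c", np.arange(10, dtype=float), 4.0)
        with pytest.raises(ValueError, match="min"):
            fit_pre_dip_regression(agg, dip_onset=5, min_span=92.0)

    def test_calibrated_noise_mean_r(self):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(17)
        rs = [fit_pre_dip_regression(gen_aggregation_trace(cfg, rng)[0]).pearson_r
              for _ in range(20)]
        assert np.mean(rs) >= 0.98


class TestRmsd:
    def test_points_on_line_give_zero(self):
        t = np.arange(30) * 4.0
        agg = AggregationTrace("c", 3.0 * t + 1.0, 4.0)
        fit = LinearFit(3.0, 1.0, 1.0, (0, 30))
        assert rmsd(agg, fit, np.arange(30)) == 0.0

    def test_alternating_unit_residuals(self):
        resid = np.array([1.0, -1.0, 1.0, -1.0])
        agg = AggregationTrace("c", resid, 4.0)
        fit = LinearFit(0.0, 0.0, 0.0, (0, 4))
        assert rmsd(agg, fit, np.arange(4)) == 1.0

    def test_chi_interval_for_iid_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(500) * 4.0
            y = 2.0 * t + 5.0 + rng.normal(0, 10.0, 500)
            agg = AggregationTrace("c", y, 4.0)
            fit = LinearFit(2.0, 5.0, 1.0, (0, 500))
            hits += 9.0 <= rmsd(agg, fit, np.arange(500)) <= 11.0
        assert hits >= 95

    def test_matches_direct_recomputation(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 80))
            y = rng.normal(0, 50, n)
            slope, intercept = rng.normal(0, 3), rng.normal(0, 100)
            agg = AggregationTrace("c", y, 4.0)
            idx = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
            fit = LinearFit(slope, intercept, 0.5, (0, n))
            assert rmsd(agg, fit, idx) == pytest.approx(
                rmsd_direct(y, agg.time, slope, intercept, idx), abs=1e-12
            )

    def test_empty_window_rejected(self):
        agg = AggregationTrace("c", np.arange(5, dtype=float), 4.0)
        with pytest.raises(ValueError):
            rmsd(agg, LinearFit(1, 0, 1, (0, 5)), [])

    def test_shift_invariance_and_gain_scaling(self, rng):
        y = rng.normal(100, 5, 50)
        agg = AggregationTrace("c", y, 4.0)
        fit = LinearFit(0.3, 20.0, 0.5, (0, 50))
        base = rmsd(agg, fit, np.arange(50))
        shifted = rmsd(AggregationTrace("c", y + 77.0, 4.0),
                       LinearFit(0.3, 97.0, 0.5, (0, 50)), np.arange(50))
        assert shifted == pytest.approx(base, rel=1e-12)
        gained = rmsd(AggregationTrace("c", y * 3.0, 4.0),
                      LinearFit(0.9, 60.0, 0.5, (0, 50)), np.arange(50))
        assert gained == pytest.approx(3 * base, rel=1e-12)


class TestRmsdTimecourse:
    def _null_trace(self, seed, onset=60, n=150):
        cfg = SyntheticConfig(post_dip_fold=1.0, n_frames=n)
        return gen_aggregation_trace(cfg, seed, dip_onset=onset)[0], onset

    def test_null_folds_near_expected(self):
        folds, nus = [], []
        for seed in range(40):
            agg, onset = self._null_trace(seed)
            fit = fit_pre_dip_regression(agg, onset)
            res = rmsd_timecourse(agg, fit, onset)
            t = agg.time
            idx = (t - t[onset] > 0) & (t - t[onset] <= 180)
            folds.append(res.fold_changes["after_3h"])
            nus.append(expected_null_fold(t[:onset], t[idx]))
        # mean fold consistent with the extrapolation-inflated null, not above it
        excess = np.asarray(folds) - np.asarray(nus)
        assert stats.ttest_1samp(excess, 0, alternative="greater").pvalue > 0.05

    def test_quadrupled_post_dip_noise_gives_fold_above_three(self):
        rng = np.random.default_rng(3)
        t = np.arange(150) * 4.0
        onset = 60
        y = 2.0 * t + 100 + rng.normal(0, 10, 150)
        y[onset + 1 :] += rng.normal(0, np.sqrt(16 - 1) * 10, 150 - onset - 1)
        agg = AggregationTrace("c", y, 4.0)
        fit = fit_pre_dip_regression(agg, onset)
        res = rmsd_timecourse(agg, fit, onset)
        assert res.max_fold >= 3.0

    def test_partial_horizon_flagged(self):
        agg, _ = self._null_trace(0, onset=130)
        fit = fit_pre_dip_regression(agg, 130)
        res = rmsd_timecourse(agg, fit, 130)
        assert res.partial
        assert len(res.rmsd_after) < 6

    def test_fold_changes_gain_invariant(self):
        agg, onset = self._null_trace(5)
        fit = fit_pre_dip_regression(agg, onset)
        res = rmsd_timecourse(agg, fit, onset)
        agg2 = AggregationTrace("c", agg.mean_intensity * 4.0, 4.0)
        fit2 = fit_pre_dip_regression(agg2, onset)
        res2 = rmsd_timecourse(agg2, fit2, onset)
        for k in res.fold_changes:
            assert res.fold_changes[k] == pytest.approx(res2.fold_changes[k], rel=1e-9)


class TestCohortRmsdReport:
    def test_all_stable_cohort_has_no_after_columns(self):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(1)
        stable = [gen_aggregation_trace(cfg, rng, cell_id=f"s{i}")[0] for i in range(5)]
        table, summary = cohort_rmsd_report([], stable)
        assert summary["n_dip_cells"] == 0
        assert (table["group"] == "stable").all()
        assert not any(c.startswith("fold_") for c in table.columns)
        assert table["rmsd_before"].notna().all()

    def test_constructed_sixty_percent_tripling(self):
        rng = np.random.default_rng(7)
        t = np.arange(150) * 4.0
        onset = 60
        cells = []
        for i in range(50):
            y = 2.0 * t + 100 + rng.normal(0, 10, 150)
            if i < 30:  # 60% of cells: residual SD x5 after the dip
                y[onset + 1 :] += rng.normal(0, np.sqrt(25 - 1) * 10, 150 - onset - 1)
            cells.append((AggregationTrace(f"c{i}", y, 4.0), onset))
        _, summary = cohort_rmsd_report(cells, [])
        assert summary["frac_fold_gt3"] == pytest.approx(0.6, abs=0.1)

    def test_cell_order_permutation_leaves_summary_unchanged(self):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(2)
        cells = [(gen_aggregation_trace(cfg, rng, dip_onset=60, cell_id=f"d{i}")[0], 60)
                 for i in range(8)]
        _, s1 = cohort_rmsd_report(cells, [])
        _, s2 = cohort_rmsd_report(cells[::-1], [])
        assert s1["mean_max_fold"] == pytest.approx(s2["mean_max_fold"])
        assert s1["median_max_fold"] == pytest.approx(s2["median_max_fold"])
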