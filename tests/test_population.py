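"""Recurrence accounting, heatmaps, population-vector correlations, the
stability score, and the circular-shift shuffle."""


import numpy as np
import pytest
from scipy import stats

from conftest import staircase_trace, staircase_trials
from remapkit.population import (
    Heatmap,
    PVCorrMatrix,
    build_heatmap_pair,
    circular_shift_shuffle,
    field_peak_distribution,
    pv_correlation,
    recurrence_ratio,
    stability_score,
)
from remapkit.tuning import ActivityRaster, TuningCurveSet


def _curveset(rates, direction="LR"):
    rates = np.asarray(rates, float)
    return TuningCurveSet(
        rates=rates, occupancy_s=np.ones(rates.shape[1]), direction=direction, n_trials=4
    )


def _heatmap(rates, direction="LR"):
    rates = np.asarray(rates, float)
    return Heatmap(rates=rates, cell_ids=np.arange(rates.shape[0]), direction=direction)


class TestRecurrenceRatio:
    def test_all_active_in_both_sessions_gives_one(self):
        sel = {(0, "LR"), (1, "RL")}
        act = {(0, "LR"), (1, "RL")}
        assert recurrence_ratio(sel, set(), act, act).RR == 1.0

    def test_all_silent_in_other_session_gives_zero(self):
        sel = {(0, "LR"), (1, "LR")}
        assert recurrence_ratio(sel, set(), sel, set()).RR == 0.0

    def test_hand_built_six_cell_scenario(self):
        # 3 recur, 2 non-recur, 1 never selective -> RR = 3/5
        sel_a = {(0, "LR"), (1, "LR"), (2, "LR"), (3, "LR")}
        sel_b = {(4, "LR")}
        act_a = {(0, "LR"), (1, "LR"), (2, "LR"), (3, "LR"), (4, "LR"), (5, "LR")}
        act_b = {(0, "LR"), (1, "LR"), (4, "LR"), (5, "LR")}
        res = recurrence_ratio(sel_a, sel_b, act_a, act_b)
        assert res.n_recurring == 3  # cells 0, 1, 4
        assert res.n_total == 5
        assert res.RR == pytest.approx(0.6)

    def test_empty_place_sets_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            recurrence_ratio(set(), set(), set(), set())


class TestHeatmaps:
    def test_identical_sessions_give_equal_heatmaps(self):
        rng = np.random.default_rng(0)
        rates = rng.gamma(2, 1, size=(10, 23))
        a, b = build_heatmap_pair(_curveset(rates), _curveset(rates), np.arange(10), "LR")
        assert np.array_equal(a.rates, b.rates)

    def test_single_cell_pair_shape(self):
        rates = np.ones((1, 23))
        a, b = build_heatmap_pair(_curveset(rates), _curveset(rates), np.array([7]), "LR")
        assert a.rates.shape == b.rates.shape == (1, 23)

    def test_rows_cosorted_by_reference_peaks(self):
        rng = np.random.default_rng(1)
        rates_a = rng.gamma(2, 1, size=(20, 23))
        rates_b = rng.gamma(2, 1, size=(20, 23))
        a, b = build_heatmap_pair(
            _curveset(rates_a), _curveset(rates_b), np.arange(20), "LR", sort_by="a"
        )
        peaks = np.argmax(a.rates, axis=1)
        assert np.all(np.diff(peaks) >= 0)
        # row identity preserved: same permutation applied to both sessions
        order = a.cell_ids
        assert np.array_equal(b.rates, rates_b[order])

    def test_empty_pair_allowed(self):
        empty = _curveset(np.empty((0, 23)))
        a, b = build_heatmap_pair(empty, empty, np.array([], dtype=int), "LR")
        assert a.n_rows == 0


class TestPVCorrelation:
    def test_self_correlation_has_unit_diagonal(self):
        rng = np.random.default_rng(2)
        hm = _heatmap(rng.gamma(2, 1, size=(15, 23)))
        mat = pv_correlation(hm, hm)
        d = np.diagonal(mat.rho)
        assert np.allclose(d[~np.isnan(d)], 1.0)

    def test_hand_computed_small_example(self):
        A = _heatmap([[1.0, 4.0], [2.0, 1.0], [5.0, 0.0]])
        B = _heatmap([[2.0, 1.0], [1.0, 3.0], [4.0, 2.0]])
        mat = pv_correlation(A, B)
        for i in range(2):
            for j in range(2):
                expected = stats.pearsonr(A.rates[:, i], B.rates[:, j]).statistic
                assert mat.rho[i, j] == pytest.approx(expected)

    def test_constant_column_is_missing(self):
        A = _heatmap([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        mat = pv_correlation(A, A)
        assert np.isnan(mat.rho[0, 0])
        assert mat.rho[1, 1] == pytest.approx(1.0)

    def test_row_shuffle_decorrelates_diagonal(self):
        rng = np.random.default_rng(3)
        rates = rng.gamma(2, 1, size=(40, 23))
        hm = _heatmap(rates)
        diag_means = []
        for _ in range(100):
            shuffled = rates[rng.permutation(40)]
            mat = pv_correlation(hm, _heatmap(shuffled))
            diag_means.append(np.nanmean(np.diagonal(mat.rho)))
        se = np.std(diag_means, ddof=1) / np.sqrt(len(diag_means))
        assert abs(np.mean(diag_means)) < 3 * se + 1e-3

    def test_single_row_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            pv_correlation(_heatmap(np.ones((1, 23))), _heatmap(np.ones((1, 23))))


class TestStabilityScore:
    def test_identity_matrices_score_one(self):
        mat = PVCorrMatrix(np.eye(23), "LR")
        s = stability_score(mat, PVCorrMatrix(np.eye(23), "RL"))
        assert s.S == pytest.approx(1.0)

    def test_constant_matrices_score_zero(self):
        mat = PVCorrMatrix(np.full((23, 23), 0.4), "LR")
        s = stability_score(mat, PVCorrMatrix(np.full((23, 23), 0.4), "RL"))
        assert s.S == pytest.approx(0.0)

    def test_hand_computed_toy_matrices(self):
        # 4x4: diagonal (.9, .8, .7, .6), off-band entries all 0.1
        rho = np.full((4, 4), 0.1)
        np.fill_diagonal(rho, [0.9, 0.8, 0.7, 0.6])
        lr = PVCorrMatrix(rho, "LR")
        rl = PVCorrMatrix(rho.copy(), "RL")
        templates = {"full": (1, 2, 3, 4)}
        s = stability_score(lr, rl, zone="full", templates=templates)
        # rho_off = 0.1; pooled diffs = (.8, .7, .6, .5) x2 -> median .65
        assert s.rho_off_LR == pytest.approx(0.1)
        assert s.S == pytest.approx(0.65)

    def test_zone_restriction_selects_bins(self):
        rho = np.zeros((23, 23))
        np.fill_diagonal(rho, np.linspace(1.0, 0.0, 23))  # high at left end
        lr = PVCorrMatrix(rho, "LR")
        rl = PVCorrMatrix(rho.copy(), "RL")
        s_l = stability_score(lr, rl, zone="L")
        s_r = stability_score(lr, rl, zone="R")
        assert s_l.S > s_r.S

    def test_invariant_to_joint_row_permutation(self):
        rng = np.random.default_rng(4)
        rates_a = rng.gamma(2, 1, size=(25, 23))
        rates_b = rates_a + rng.normal(0, 0.3, size=(25, 23))
        perm = rng.permutation(25)
        m1 = {d: pv_correlation(_heatmap(rates_a, d), _heatmap(rates_b, d))
              for d in ("LR", "RL")}
        m2 = {d: pv_correlation(_heatmap(rates_a[perm], d), _heatmap(rates_b[perm], d))
              for d in ("LR", "RL")}
        s1 = stability_score(m1["LR"], m1["RL"])
        s2 = stability_score(m2["LR"], m2["RL"])
        assert s1.S == pytest.approx(s2.S)

    def test_all_missing_peridiagonal_raises(self):
        rho = np.full((23, 23), np.nan)
        with pytest.raises(ValueError):
            stability_score(PVCorrMatrix(rho, "LR"), PVCorrMatrix(rho.copy(), "RL"))


class TestCircularShiftShuffle:
    def test_conserves_per_cell_per_trial_counts(self):
        rng = np.random.default_rng(5)
        trace = staircase_trace(n_trials=4)
        trials = staircase_trials(n_trials=4)
        raster = ActivityRaster(rng.integers(0, 3, size=(6, trace.n_frames)), 11.0)
        shuffled = circular_shift_shuffle(raster, trials, seed=1)
        for tr in trials:
            s, e = tr.start_frame, tr.end_frame + 1
            assert np.array_equal(
                raster.spikes[:, s:e].sum(axis=1), shuffled.spikes[:, s:e].sum(axis=1)
            )

    def test_frames_outside_trials_untouched(self):
        rng = np.random.default_rng(6)
        trace = staircase_trace(n_trials=4)
        trials = staircase_trials(n_trials=2)  # last two trials left out
        raster = ActivityRaster(rng.integers(0, 2, size=(3, trace.n_frames)), 11.0)
        shuffled = circular_shift_shuffle(raster, trials, seed=2)
        outside = np.ones(trace.n_frames, dtype=bool)
        for tr in trials:
            outside[tr.start_frame : tr.end_frame + 1] = False
        assert np.array_equal(raster.spikes[:, outside], shuffled.spikes[:, outside])

    def test_zero_offsets_are_identity(self):
        class ZeroRng:
            def integers(self, low, high, size=None):
                return np.zeros(size, dtype=int)

        trace = staircase_trace(n_trials=2)
        trials = staircase_trials(n_trials=2)
        spikes = np.arange(2 * trace.n_frames).reshape(2, -1)
        raster = ActivityRaster(spikes, 11.0)
        shuffled = circular_shift_shuffle(raster, trials, seed=ZeroRng())
        assert np.array_equal(raster.spikes, shuffled.spikes)


class TestFieldPeakDistribution:
    def test_all_rows_peaked_at_same_bin(self):
        rates = np.zeros((10, 23))
        rates[:, 4] = 1.0
        hist = field_peak_distribution(_heatmap(rates))
        assert hist[4] == 10 and hist.sum() == 10

    def test_uniform_peaks_pass_chi_square(self):
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rates = np.zeros((230, 23))
            rates[np.arange(230), rng.integers(0, 23, 230)] = 1.0
            hist = field_peak_distribution(_heatmap(rates))
            p = stats.chisquare(hist).pvalue
            passed += int(p > 0.01)
        assert passed >= 18

    def test_tie_goes_to_lowest_bin(self):
        rates = np.ones((1, 23))
        assert field_peak_distribution(_heatmap(rates))[0] == 1
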