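"""Shock-zone entries, Poisson response detection, and peak-side analysis."""

import math

import numpy as np
import pytest

from remapkit import SimConfig, generate_population, generate_shock_session
from remapkit.behavior import PositionTrace
from remapkit.shock import (
    ZoneEntry,
    approach_departure_side,
    classify_shock_response,
    detect_zone_entries,
    poisson_threshold,
    population_shock_average,
    reflect_curve,
)


def _trace(x, fps=11.0):
    x = np.asarray(x, float)
    return PositionTrace(t=np.arange(x.size) / fps, x=x, frame_rate=fps)


def brute_force_threshold(lam, alpha=0.01):
    """Independent oracle: smallest k with sum_{j>=k} e^-lam lam^j / j! < alpha."""
    k = 0
    while True:
        tail = 1.0 - sum(
            math.exp(-lam) * lam**j / math.factorial(j) for j in range(k)
        )
        if tail < alpha:
            return k
        k += 1


def _entry(frame, direction="LR", electrified=False, win=22, n_frames=10_000):
    stop = min(frame + win, n_frames)
    return ZoneEntry(frame, direction, electrified, (frame, stop))


class TestDetectZoneEntries:
    def test_no_zone_visit_gives_empty(self):
        tr = _trace(np.linspace(0, 80, 50))
        assert detect_zone_entries(tr, (100, 150), None) == []

    def test_pre_and_post_electrification_entries(self):
        x = np.concatenate([np.linspace(0, 250, 60), np.linspace(250, 0, 60)])
        tr = _trace(x)
        shock_on = tr.t[70]
        entries = detect_zone_entries(tr, (100, 150), shock_on)
        assert len(entries) == 2
        assert [e.electrified for e in entries] == [False, True]
        assert [e.direction for e in entries] == ["LR", "RL"]

    def test_k_passes_give_k_entries(self):
        legs = []
        for k in range(8):
            ramp = np.linspace(0, 250, 40)
            legs.append(ramp if k % 2 == 0 else ramp[::-1])
        entries = detect_zone_entries(_trace(np.concatenate(legs)), (100, 150), None)
        assert len(entries) == 8

    def test_window_spans_two_seconds(self):
        tr = _trace(np.linspace(0, 250, 300))
        entries = detect_zone_entries(tr, (100, 150), 0.0)
        e = entries[0]
        assert e.n_frames == math.ceil(2 * 11.0)


class TestPoissonThreshold:
    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0, 2.0, 5.5, 12.0])
    def test_matches_brute_force_tail_sums(self, lam):
        assert poisson_threshold(lam) == brute_force_threshold(lam)

    def test_lambda_two_example(self):
        # P(X>=7 | 2) ~ 0.0045 < 0.01, P(X>=6 | 2) ~ 0.0166 > 0.01 -> k = 7
        k = poisson_threshold(2.0)
        assert k == brute_force_threshold(2.0) == 7


class TestClassifyShockResponse:
    def test_no_electrified_entries_raises(self):
        active = np.zeros(1000, dtype=bool)
        with pytest.raises(ValueError, match="no shock entries"):
            classify_shock_response(active, [_entry(10)])

    def test_no_direction_matched_baseline_raises(self):
        active = np.zeros(1000, dtype=bool)
        entries = [_entry(10, "RL"), _entry(200, "LR", electrified=True)]
        with pytest.raises(ValueError, match="no baseline"):
            classify_shock_response(active, entries)

    def test_burst_on_first_entry_is_responsive(self):
        active = np.zeros(2000, dtype=bool)
        active[500:515] = True  # 15 active frames in electrified window
        entries = [_entry(10), _entry(100), _entry(500, electrified=True)]
        lab = classify_shock_response(active, entries)
        assert lab.responsive
        assert lab.first_significant_entry == 1
        assert lab.trigger_counts[0] == 15

    def test_third_entry_burst_does_not_count(self):
        active = np.zeros(3000, dtype=bool)
        active[900:915] = True  # burst only on the third electrified entry
        entries = [
            _entry(10),
            _entry(500, electrified=True),
            _entry(700, electrified=True),
            _entry(900, electrified=True),
        ]
        lab = classify_shock_response(active, entries)
        assert not lab.responsive
        assert lab.first_significant_entry is None

    def test_zero_baseline_uses_floor_lambda(self):
        active = np.zeros(2000, dtype=bool)
        entries = [_entry(10), _entry(100), _entry(500, electrified=True)]
        lab = classify_shock_response(active, entries)
        # floor: 1 active frame per 44 baseline frames -> lambda = 22/44
        assert lab.baseline_lambda == pytest.approx(0.5)
        assert lab.threshold_k == brute_force_threshold(0.5)

    def test_baseline_lambda_is_mean_window_count(self):
        active = np.zeros(2000, dtype=bool)
        active[10:14] = True  # 4 active frames in first baseline window
        active[100:102] = True  # 2 in second
        entries = [_entry(10), _entry(100), _entry(500, electrified=True)]
        lab = classify_shock_response(active, entries)
        assert lab.baseline_lambda == pytest.approx(3.0)

    def test_null_false_positive_rate_with_unit_gain(self):
        cfg = SimConfig(
            n_cells=200, untuned_fraction=1.0, baseline_rate=1.0, shock_gain=1.0,
            n_trials_per_direction=14, seed=21, shock_responsive_frac=1.0,
        )
        pop = generate_population(cfg)
        sess = generate_shock_session(pop, cfg)
        entries = detect_zone_entries(sess.trace, sess.events.shock_zone,
                                      sess.events.shock_on_time)
        active = sess.raster.active
        n_sig = n_tested = 0
        for c in range(cfg.n_cells):
            lab = classify_shock_response(active[c], entries)
            n_tested += len(lab.trigger_counts)
            n_sig += sum(
                count >= lab.threshold_k for count in lab.trigger_counts
            )
        assert n_sig / n_tested <= 0.02

    def test_power_with_strong_gain(self):
        cfg = SimConfig(
            n_cells=200, untuned_fraction=1.0, baseline_rate=0.5, shock_gain=20.0,
            n_trials_per_direction=14, seed=22, shock_responsive_frac=1.0,
        )
        pop = generate_population(cfg)
        sess = generate_shock_session(pop, cfg)
        entries = detect_zone_entries(sess.trace, sess.events.shock_zone,
                                      sess.events.shock_on_time)
        active = sess.raster.active
        detected = sum(
            classify_shock_response(active[c], entries).responsive
            for c in range(cfg.n_cells)
        )
        assert detected / cfg.n_cells > 0.9


class TestApproachDeparture:
    def test_lr_peak_left_of_center_is_approach(self):
        rates = np.zeros(23)
        rates[2] = 5.0  # bin 3
        assert approach_departure_side(rates, "LR") == "approach"

    def test_rl_peak_reflects_to_departure(self):
        rates = np.zeros(23)
        rates[2] = 5.0  # bin 3 reflects to bin 21
        assert approach_departure_side(rates, "RL") == "departure"

    def test_center_peak_resolved_by_area(self):
        rates = np.zeros(23)
        rates[12] = 5.0  # bin 13
        rates[:12] = 4.0 / 12  # area 4.0 on approach side
        rates[13:] = 2.5 / 10  # area 2.5 on departure side
        assert approach_departure_side(rates, "LR") == "approach"
        rates2 = rates.copy()
        rates2[:12], rates2[13:] = 2.5 / 12, 4.0 / 10
        assert approach_departure_side(rates2, "LR") == "departure"

    def test_reflection_is_an_involution(self):
        rng = np.random.default_rng(7)
        rates = rng.gamma(2, 1, 23)
        assert np.array_equal(reflect_curve(reflect_curve(rates)), rates)


class TestPopulationShockAverage:
    def test_single_responder_average_is_its_window(self):
        active = np.zeros((1, 1000), dtype=bool)
        active[0, 500:510] = True
        entries = [_entry(10), _entry(100), _entry(500, electrified=True, n_frames=1000)]
        lab = classify_shock_response(active[0], entries)
        avg = population_shock_average(active, entries, [lab], frame_rate=11.0)
        n_pre = math.ceil(2 * 11.0)
        expected = active[0, 500 - n_pre : 500 + n_pre].astype(float) * 11.0
        assert np.allclose(avg, expected)

    def test_responders_show_post_entry_burst(self):
        cfg = SimConfig(
            n_cells=150, untuned_fraction=1.0, baseline_rate=0.5, shock_gain=10.0,
            n_trials_per_direction=14, seed=23, shock_responsive_frac=1.0,
        )
        pop = generate_population(cfg)
        sess = generate_shock_session(pop, cfg)
        entries = detect_zone_entries(sess.trace, sess.events.shock_zone,
                                      sess.events.shock_on_time)
        active = sess.raster.active
        labels = [classify_shock_response(active[c], entries)
                  for c in range(cfg.n_cells)]
        responders = [c for c, lab in enumerate(labels) if lab.responsive]
        avg = population_shock_average(
            active[responders], entries, [labels[c] for c in responders],
            frame_rate=cfg.frame_rate,
        )
        n_pre = math.ceil(2 * cfg.frame_rate)
        assert np.nanmean(avg[n_pre:]) > 3 * max(np.nanmean(avg[:n_pre]), 0.1)

    def test_empty_cell_set_raises(self):
        with pytest.raises(ValueError):
            population_shock_average(np.zeros((0, 10)), [_entry(1, electrified=True)],
                                     [], frame_rate=11.0)
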