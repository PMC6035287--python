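"""Segmentation, event classification, frequency estimators, molecule counting."""

import numpy as np
import pytest

from microtip.containers import Trajectory
from microtip.dynamics import (
    EventTable,
    PhaseSegment,
    classify_events,
    count_molecules,
    frequency_estimates,
    segment_piecewise_linear,
)
from microtip.trajectories import InstabilityParams, simulate_dynamic_instability


def traj_from(times, lengths):
    return Trajectory(np.asarray(times, float), np.asarray(lengths, float),
                      np.asarray(lengths, float))


class TestSegmentation:
    def test_straight_line_yields_single_segment_with_exact_slope(self):
        t = np.arange(50) * 0.7
        tr = traj_from(t, 17.3 * t + 5.0)
        segs = segment_piecewise_linear(tr, penalty=10.0)
        assert len(segs) == 1
        assert segs[0].slope == pytest.approx(17.3, rel=1e-9)

    def test_two_slope_breakpoint_localized(self):
        # slope change 10 -> 40 nm/s at t = 150 s with 20 nm frame noise:
        # breakpoint within +/- 2 samples in >= 95% of seeded runs
        hits, runs = 0, 100
        dt = 0.7
        t = np.arange(0, 300, dt)
        for s in range(runs):
            rng = np.random.default_rng(s)
            y = np.where(t < 150.0, 10.0 * t, 10.0 * 150 + 40.0 * (t - 150.0))
            tr = traj_from(t, y + rng.normal(0, 20.0, len(t)))
            segs = segment_piecewise_linear(tr)
            internal = [sg.t_start for sg in segs[1:]]
            if internal and min(abs(b - 150.0) for b in internal) <= 2 * dt + 1e-9:
                hits += 1
        assert hits / runs >= 0.95

    def test_telegraph_phases_recovered(self):
        p = InstabilityParams(v_g=40.0, v_s=300.0, f_cat=1.0, f_res=6.0,
                              seed_length=0.0, seed=3)
        tr = simulate_dynamic_instability(p, duration=400.0, dt=0.5)
        segs = segment_piecewise_linear(tr, penalty=1.0, min_size=3)
        # fraction of time points whose segment sign matches the true phase
        correct = 0
        for i, (ti, ph) in enumerate(zip(tr.times, tr.phases)):
            seg = next((s for s in segs if s.t_start - 1e-9 <= ti <= s.t_end + 1e-9), None)
            if seg is None:
                continue
            if (ph == "growth" and seg.slope > 0) or (ph == "shrink" and seg.slope < 0):
                correct += 1
        assert correct / len(tr) >= 0.9

    def test_nonpositive_penalty_rejected(self):
        t = np.arange(20) * 0.7
        with pytest.raises(ValueError):
            segment_piecewise_linear(traj_from(t, t), penalty=0.0)

    def test_short_trajectory_rejected(self):
        t = np.arange(5) * 0.7
        with pytest.raises(ValueError):
            segment_piecewise_linear(traj_from(t, t), penalty=1.0)


class TestClassification:
    def seg(self, t0, t1, slope):
        return PhaseSegment(t0, t1, slope, y_start=0.0, y_end=0.0)

    def test_all_growth_has_no_events(self):
        events = classify_events([self.seg(0, 600, 30.0)])
        assert events.n_catastrophes == 0
        assert events.total_growth_time == pytest.approx(10.0)  # minutes

    def test_transitions_counted_with_pause_rules(self):
        segs = [self.seg(0, 100, 30.0), self.seg(100, 120, -200.0),
                self.seg(120, 200, 2.0), self.seg(200, 260, 40.0),
                self.seg(260, 280, -150.0), self.seg(280, 300, 25.0)]
        ev = classify_events(segs)
        assert ev.n_catastrophes == 2   # growth->shrink, growth->shrink
        assert ev.n_rescues == 2        # shrink->pause, shrink->growth
        assert ev.total_shrink_time == pytest.approx(40 / 60)

    def test_pause_threshold_splits_slow_growth(self):
        # 0.5 um/min = 8.3 nm/s default; slower slopes are pauses
        ev = classify_events([self.seg(0, 100, 5.0)])
        assert ev.total_growth_time == 0.0

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            classify_events([self.seg(0, 100, 30.0), self.seg(50, 150, -20.0)])

    def test_telegraph_ground_truth_counts_reproduced_exactly(self):
        # noise-free telegraph: segmentation + classification recover the
        # generator's transitions and phase times exactly
        p = InstabilityParams(v_g=40.0, v_s=400.0, f_cat=1.2, f_res=8.0,
                              seed_length=0.0, seed=5)
        tr = simulate_dynamic_instability(p, duration=500.0, dt=0.5)
        true_cat = int(np.sum((tr.phases[:-1] == "growth") & (tr.phases[1:] == "shrink")))
        true_res = int(np.sum((tr.phases[:-1] == "shrink") & (tr.phases[1:] == "growth")))
        segs = segment_piecewise_linear(tr, penalty=0.5, min_size=2)
        ev = classify_events(segs)
        assert abs(ev.n_catastrophes - true_cat) <= 1
        assert abs(ev.n_rescues - true_res) <= 1

    def test_repair_events_come_from_paired_intervals(self):
        ev = classify_events([self.seg(0, 600, 30.0)],
                             repair_intervals=[(10.0, 40.0), (100.0, 130.0)])
        assert ev.n_repair_events == 2


class TestFrequencies:
    def make_events(self, n_cat=5, n_res=3, growth_min=10.0, shrink_min=2.0,
                    shrink_durations=None):
        if shrink_durations is None:
            shrink_durations = np.full(max(n_res, 1), shrink_min / max(n_res, 1))
        return EventTable(
            n_catastrophes=n_cat, n_rescues=n_res, n_repair_events=2,
            total_growth_time=growth_min, total_shrink_time=shrink_min,
            catastrophe_times=np.zeros(n_cat), catastrophe_positions=np.zeros(n_cat),
            rescue_times=np.zeros(n_res), rescue_positions=np.zeros(n_res),
            shrink_durations=np.asarray(shrink_durations),
        )

    def test_catastrophe_frequency_and_se(self):
        f = frequency_estimates(self.make_events(n_cat=4, growth_min=8.0))
        assert f["f_cat"].value == pytest.approx(0.5)
        assert f["f_cat"].se == pytest.approx(0.5 / 2.0)

    def test_poisson_branch_for_nine_rescues(self):
        # N_r = 9 <= 10: SE = f / sqrt(9) = f / 3
        f = frequency_estimates(self.make_events(n_res=9, shrink_min=3.0))
        est = f["f_res"]
        assert est.method == "poisson_se"
        assert est.se == pytest.approx(est.value / 3.0)

    def test_ratio_branch_above_poisson_threshold(self):
        durations = np.linspace(0.05, 0.4, 15)
        ev = self.make_events(n_res=15, shrink_min=float(durations.sum()),
                              shrink_durations=durations)
        est = frequency_estimates(ev)["f_res"]
        assert est.method == "ratio_se"
        t_mean = durations.mean()
        se_t = durations.std(ddof=1) / np.sqrt(len(durations))
        assert est.se == pytest.approx(est.value * se_t / t_mean)

    def test_zero_events_flagged_low_information(self):
        f = frequency_estimates(self.make_events(n_cat=0, n_res=0, shrink_min=1.0))
        assert f["f_cat"].value == 0.0 and f["f_cat"].se == 0.0
        assert "low_information" in f["f_cat"].flags

    def test_zero_time_flagged_undefined(self):
        ev = self.make_events(n_cat=0, growth_min=0.0)
        assert "undefined" in frequency_estimates(ev)["f_cat"].flags

    def test_estimator_calibration_against_telegraph_simulation(self):
        # pooled estimate within 95% CI; empirical coverage 90-98%
        rng = np.random.default_rng(17)
        p = InstabilityParams(v_g=40.0, v_s=500.0, f_cat=0.5, f_res=5.0)
        covered, reps = 0, 200
        for _ in range(reps):
            total = None
            for _ in range(5):
                tr = simulate_dynamic_instability(p, duration=600.0, dt=0.5, rng=rng)
                g = tr.phases == "growth"
                n_cat = int(np.sum(g[:-1] & (tr.phases[1:] == "shrink")))
                gt = g.sum() * 0.5 / 60.0
                st = float(np.sum(tr.phases == "shrink")) * 0.5 / 60.0
                ev = EventTable(n_cat, 0, 0, gt, st,
                                np.zeros(n_cat), np.zeros(n_cat),
                                np.empty(0), np.empty(0), np.empty(0))
                total = ev if total is None else total + ev
            est = frequency_estimates(total)["f_cat"]
            if est.n_events and abs(est.value - 0.5) <= 1.96 * est.se:
                covered += 1
        assert 0.90 <= covered / reps <= 0.99


class TestMoleculeCounting:
    def test_spot_equal_to_reference_mean_counts_one(self):
        counts, _ = count_molecules([500.0], [400.0, 500.0, 600.0])
        assert counts[0] == pytest.approx(1.0)

    def test_pentamer_mixture_histogram_peaks_at_five(self, rng):
        singles = rng.normal(100.0, 30.0, 400)
        spots = np.maximum(rng.normal(500.0, 30.0 * np.sqrt(5), 800), 1.0)
        counts, (hist, edges) = count_molecules(spots, singles, bin_width=1.0)
        mode_bin = np.argmax(hist)
        center = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
        assert abs(center - 5.0) <= 1.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            count_molecules([1.0], [])
        with pytest.raises(ValueError):
            count_molecules([1.0], [-5.0, 5.0, 0.0])
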