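"""Outcome extraction and validity gating for the four tests."""

import numpy as np
import pytest

from ergocap import (
    AnalysisError,
    AthleteProfile,
    BreathRecord,
    WheelGeometry,
    analyze_gxt,
    analyze_isometric,
    analyze_sprint,
    analyze_wingate,
    check_secondary_criteria,
    detect_termination,
)
from ergocap.protocol import GxtStage
from ergocap.simulate import synth_isometric_trials
from ergocap.validation import reference_athlete

from conftest import (GEOMETRY, UNIT_GEOMETRY, brute_force_max_window_mean,
                      const_trace, make_trace)


def force_to_torque(force):
    """Per-side torque producing the given side-averaged force."""
    return force * GEOMETRY.rim_radius


class TestIsometric:
    def test_constant_force_identity(self, profile):
        trace = const_trace(5.0, force_to_torque(262.0), 0.0)
        res = analyze_isometric([trace], profile)
        assert res.f_iso == pytest.approx(262.0)
        assert res.f_iso_per_kg == pytest.approx(3.91, abs=0.005)

    def test_max_over_trials(self, profile):
        trials = [const_trace(5.0, force_to_torque(f), 0.0) for f in (80, 90, 84)]
        res = analyze_isometric(trials, profile)
        assert res.f_iso == pytest.approx(90.0)
        assert res.best_trial == 1

    def test_ramp_hold_release_recovers_plateau(self, profile):
        gt = reference_athlete(mass_user=profile.mass_user, f_iso=300.0)
        trials = synth_isometric_trials(gt, seed=0, noise=0.0)
        res = analyze_isometric(trials, profile)
        assert res.f_iso == pytest.approx(300.0, abs=1.0)

    def test_short_trial_rejected(self, profile):
        with pytest.raises(AnalysisError, match="3"):
            analyze_isometric([const_trace(2.0, 10.0, 0.0)], profile)

    def test_clipping_raises_saturation_flag(self, profile):
        gt = reference_athlete(mass_user=profile.mass_user, f_iso=300.0)
        clipped = synth_isometric_trials(gt, seed=1, force_limit=200.0)
        honest = synth_isometric_trials(gt, seed=1)
        assert analyze_isometric(clipped, profile).saturation_flag
        assert not analyze_isometric(honest, profile).saturation_flag


class TestSprint:
    def test_constant_power_identity(self):
        trace = const_trace(11.0, torque=15.5, velocity=3.0)
        res = analyze_sprint([trace], trim=False)
        total = 2 * 15.5 * 3.0 / GEOMETRY.wheel_radius
        assert res.po_mean == pytest.approx(total)
        assert res.po_max == pytest.approx(total)
        assert res.v_mean == pytest.approx(3.0)
        assert res.v_max == pytest.approx(3.0)

    def test_trial_with_highest_v_max_selected(self):
        slow = const_trace(11.0, 10.0, 4.0)
        fast = const_trace(11.0, 8.0, 4.2)
        res = analyze_sprint([slow, fast], trim=False)
        assert res.best_trial == 1
        assert res.v_mean == pytest.approx(4.2)

    def test_accelerating_sprint_matches_sample_mean(self):
        rng = np.random.default_rng(3)
        n = 1101
        t = np.arange(n) / 100.0
        vel = 4.0 * (1 - np.exp(-t / 3.0)) + 0.01
        torque = rng.uniform(8, 20, n)
        trace = make_trace(torque, torque, vel, vel)
        res = analyze_sprint([trace], trim=False)
        total = 2 * torque * vel / GEOMETRY.wheel_radius
        assert res.po_mean == pytest.approx(np.mean(total[:1000]))
        assert res.po_max == pytest.approx(np.max(total[:1000]))

    def test_short_trial_rejected(self):
        with pytest.raises(AnalysisError, match="10"):
            analyze_sprint([const_trace(6.0, 10.0, 2.0)], trim=False)


class TestWingate:
    def test_constant_identity(self):
        v, torque = 2.0, 139.0 * UNIT_GEOMETRY.wheel_radius / (2 * 2.0)
        trace = const_trace(31.0, torque, v, geometry=UNIT_GEOMETRY)
        res = analyze_wingate(trace, trim=False)
        assert res.p30 == pytest.approx(139.0)
        assert res.p5 == pytest.approx(139.0)
        assert res.po_max == pytest.approx(139.0)

    @pytest.mark.parametrize("velocity,valid", [(2.6, True), (3.1, False)])
    def test_rim_velocity_validity_threshold(self, velocity, valid):
        trace = const_trace(31.0, 10.0, velocity, geometry=UNIT_GEOMETRY)
        res = analyze_wingate(trace, trim=False)
        assert res.v_max_rim == pytest.approx(velocity)
        assert res.valid is valid

    def test_exact_limit_is_invalid(self):
        trace = const_trace(31.0, 10.0, 3.0, geometry=UNIT_GEOMETRY)
        assert analyze_wingate(trace, trim=False).valid is False

    def test_p5_matches_brute_force_on_decaying_profile(self):
        rng = np.random.default_rng(4)
        n = 3101
        decay = np.linspace(1.6, 0.6, n)
        torque = 20.0 * decay * (1 + 0.2 * rng.standard_normal(n))
        trace = make_trace(torque, torque, np.full(n, 2.0), np.full(n, 2.0))
        res = analyze_wingate(trace, trim=False)
        total = 2 * torque * 2.0 / GEOMETRY.wheel_radius
        assert res.p5 == pytest.approx(
            brute_force_max_window_mean(total[:3000], 500))

    def test_outcome_ordering_on_random_traces(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = 321
            torque = rng.uniform(1, 30, n)
            vel = rng.uniform(0.5, 3.0, n)
            trace = make_trace(torque, torque, vel, vel, sample_rate=10.0)
            res = analyze_wingate(trace, trim=False)
            assert res.po_max >= res.p5 >= res.p30 >= 0


class TestTermination:
    def test_target_held_returns_end_of_trace(self):
        trace = const_trace(100.0, 10.0, 2.0)
        assert detect_termination(trace, 2.0) == pytest.approx(trace.time[-1])

    def test_sustained_drop_detected_at_crossing(self):
        n = 60001
        vel = np.full(n, 2.0)
        vel[50000:] = 1.70  # 0.30 below target from t = 500 s
        trace = make_trace(np.ones(n), np.ones(n), vel, vel)
        assert detect_termination(trace, 2.0) == pytest.approx(500.0)

    def test_brief_dip_is_ignored(self):
        n = 10001
        vel = np.full(n, 2.0)
        vel[4000:4150] = 1.6  # 1.5 s dip < 3 s dwell
        trace = make_trace(np.ones(n), np.ones(n), vel, vel)
        assert detect_termination(trace, 2.0) == pytest.approx(trace.time[-1])


class TestGxt:
    def stages(self, n=10, power=90.0):
        return [GxtStage(k, power * (0.2 + 0.08 * (k - 1)) / 1.0, 0.01)
                for k in range(1, n + 1)]

    def test_constant_final_block(self, profile):
        torque = 90.0 * GEOMETRY.wheel_radius / (2 * 2.0)
        trace = const_trace(600.0, torque, 2.0)
        res = analyze_gxt(trace, self.stages(), profile)
        assert res.po_peak == pytest.approx(90.0)
        assert res.duration == pytest.approx(10.0)
        assert res.duration_valid

    @pytest.mark.parametrize("minutes,valid", [
        (7.0, False), (7.94, False), (8.0, True), (10.0, True),
        (12.0, True), (12.04, True), (12.6, False),
    ])
    def test_duration_validity_window(self, profile, minutes, valid):
        trace = const_trace(minutes * 60.0, 10.0, 2.0)
        res = analyze_gxt(trace, self.stages(n=14), profile)
        assert res.duration == pytest.approx(minutes)
        assert res.duration_valid is valid

    def test_mid_stage_termination_matches_brute_force(self, profile):
        # rising power, ends 36 s into stage 9: windows confined to stage 9
        rng = np.random.default_rng(6)
        n = 5161  # 516 s at 10 Hz
        t = np.arange(n) / 10.0
        torque = (5.0 + 0.02 * t) * (1 + 0.1 * rng.standard_normal(n))
        vel = np.full(n, 2.0)
        trace = make_trace(torque, torque, vel, vel, sample_rate=10.0)
        res = analyze_gxt(trace, self.stages(), profile)
        assert res.final_block == 9
        total = 2 * torque * 2.0 / GEOMETRY.wheel_radius
        in_block = (t >= 480.0) & (t < 516.0)
        assert res.po_peak == pytest.approx(
            brute_force_max_window_mean(total[in_block], 300))

    def test_short_final_stage_falls_back_to_completed(self, profile):
        # ends 10 s into stage 9 -> outcomes from stage 8
        trace = const_trace(490.0, 10.0, 2.0)
        res = analyze_gxt(trace, self.stages(), profile)
        assert res.final_block == 8

    def test_breath_outcomes_match_brute_force(self, profile):
        rng = np.random.default_rng(7)
        times = np.cumsum(rng.uniform(1.5, 2.5, 200))
        vo2 = 800 + 8.0 * times + 50 * rng.standard_normal(200)
        breaths = [BreathRecord(t, v, 1.0 + 0.0004 * t, 100 + 0.1 * t)
                   for t, v in zip(times, vo2)]
        trace = const_trace(420.0, 10.0, 2.0)
        res = analyze_gxt(trace, self.stages(), profile, breaths=breaths,
                          rpe_peripheral=8, rpe_central=6)
        kept = [b for b in breaths if b.time <= 420.0]
        bt = np.array([b.time for b in kept])
        bv = np.array([b.vo2 for b in kept])
        best = -np.inf
        for i in range(len(kept)):
            if bt[i] - bt[0] < 30.0:
                continue
            j = int(np.searchsorted(bt, bt[i] - 30.0, side="right"))
            best = max(best, float(np.mean(bv[j:i + 1])))
        assert res.vo2peak == pytest.approx(best / profile.mass_user)
        assert res.hr_peak == pytest.approx(max(b.hr for b in kept))
        assert res.rpe_overall == pytest.approx(7.0)


class TestSecondaryCriteria:
    def test_all_three_met(self):
        res = check_secondary_criteria(1.15, 190.0, 9.0, age=26.0)
        assert res.hr_threshold == pytest.approx(165.3)
        assert res.met and res.rer_met and res.hr_met and res.rpe_met

    def test_one_of_three_not_met(self):
        res = check_secondary_criteria(1.05, 150.0, 9.0, age=30.0)
        assert not res.met
        assert res.rpe_met and not res.rer_met and not res.hr_met

    def test_lesion_excludes_hr_criterion(self):
        res = check_secondary_criteria(1.12, None, 8.0, age=30.0,
                                       lesion_above_T5=True)
        assert res.met
        assert res.hr_met is None
        # with the exclusion, BOTH remaining criteria must hold
        res2 = check_secondary_criteria(1.12, None, 6.0, age=30.0,
                                        lesion_above_T5=True)
        assert not res2.met
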