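import numpy as np
import pytest

from deerloop.delay_planner import (PulseCollisionError, SensitivityPlan,
                                    SequencePlan, SplitMeasurementError,
                                    TargetUnreachableError, assemble_delays,
                                    choose_time_step, optimal_tau_evo,
                                    planning_curve, r_min_for_dt,
                                    required_snr, select_sequence, snr_curve,
                                    tau_evo_for_target)
from deerloop.relaxation_analysis import DecayFit


class TestTimeStep:
    def test_default_8ns_gives_1p25nm(self):
        plan = choose_time_step()
        assert plan.dt == 8.0
        assert plan.r_min_detectable == pytest.approx(1.25, abs=0.01)

    def test_16ns_gives_1p58nm(self):
        assert r_min_for_dt(16.0) == pytest.approx(1.58, abs=0.005)

    def test_cube_root_scaling(self):
        assert r_min_for_dt(64.0) == pytest.approx(2 * r_min_for_dt(8.0),
                                                   rel=1e-12)

    def test_awg_limit_escalates_in_doublings(self):
        plan = choose_time_step(awg_point_limit=300, tau_evo_ns=4000.0)
        assert plan.dt == 16.0 and plan.awg_limited

    def test_dt_above_16_warns(self):
        plan = choose_time_step(awg_point_limit=150, tau_evo_ns=4000.0)
        assert plan.dt == 32.0
        assert any("distortion" in w for w in plan.warnings)

    def test_expect_short_hard_warning(self):
        plan = choose_time_step(awg_point_limit=150, tau_evo_ns=4000.0,
                                expect_short=True)
        assert any(w.startswith("SHORT DISTANCES") for w in plan.warnings)

    def test_split_measurement_error(self):
        with pytest.raises(SplitMeasurementError):
            choose_time_step(awg_point_limit=50, tau_evo_ns=4000.0)


class TestTauEvoRule:
    def test_identity_at_reference_length(self):
        assert tau_evo_for_target(5.0, "mean") == pytest.approx(2000.0)

    def test_presence_vs_shape_ratio_is_8(self):
        r = 4.7
        assert tau_evo_for_target(r, "presence") * 8 == pytest.approx(
            tau_evo_for_target(r, "shape"), rel=1e-12)

    def test_monotone_in_information_level(self):
        taus = [tau_evo_for_target(4.0, lvl)
                for lvl in ("presence", "mean", "width", "shape")]
        assert taus == sorted(taus)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            tau_evo_for_target(-1.0, "mean")


class TestRequiredSnr:
    @pytest.mark.parametrize("mnr,lam,expected", [(150, 0.5, 300),
                                                  (20, 0.1, 200),
                                                  (80, 1.0, 80)])
    def test_quotient(self, mnr, lam, expected):
        assert required_snr(mnr, lam) == expected

    def test_zero_lambda_flagged(self):
        with pytest.raises(ValueError, match="modulation absent"):
            required_snr(150, 0.0)


class TestSnrCurve:
    DECAY = DecayFit(Tm=6.0, xi_m=1.1, A=1.0)

    def _plan(self, T_h=2.0, sigma=1.0, decay_sigma=0.01):
        return SensitivityPlan(T_h=T_h, srt_ms=3.0, dt_ns=8.0, sigma=sigma,
                               decay_sigma=decay_sigma)

    def test_doubling_time_scales_sqrt2(self):
        tau = np.array([1000.0, 3000.0, 6000.0])
        s1 = snr_curve(self.DECAY, self._plan(T_h=2.0))(tau)
        s2 = snr_curve(self.DECAY, self._plan(T_h=4.0))(tau)
        np.testing.assert_allclose(s2, np.sqrt(2) * s1, rtol=1e-12)

    def test_vanishing_noise_hits_max_bound(self):
        tau = optimal_tau_evo(self.DECAY, self._plan(sigma=1e-9,
                                                     decay_sigma=0.0),
                              target_snr=100.0,
                              tau_bounds_ns=(200.0, 15000.0))
        assert tau == 15000.0

    def test_lower_band_never_exceeds_central(self):
        plan = self._plan(decay_sigma=0.05)
        t_lo = optimal_tau_evo(self.DECAY, plan, 40.0)
        t_ce = optimal_tau_evo(self.DECAY, plan, 40.0,
                               use_lower_band=False)
        assert t_lo <= t_ce

    def test_bisection_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            decay = DecayFit(Tm=rng.uniform(2, 12),
                             xi_m=rng.uniform(0.8, 1.6), A=1.0)
            plan = self._plan(T_h=rng.uniform(0.5, 8),
                              sigma=rng.uniform(0.5, 2),
                              decay_sigma=rng.uniform(0, 0.05))
            target = rng.uniform(20, 120)
            snr = snr_curve(decay, plan, "lower")
            taus = np.arange(200.0, 20000.0, 1.0)
            ok = snr(taus) >= target
            try:
                tau = optimal_tau_evo(decay, plan, target)
            except TargetUnreachableError:
                assert not ok.any()
                continue
            oracle = taus[np.nonzero(ok)[0].max()] if ok.any() else None
            assert oracle is not None
            assert abs(tau - oracle) <= plan.dt_ns + 1.0

    def test_unreachable_target_reports_achievable(self):
        with pytest.raises(TargetUnreachableError) as err:
            optimal_tau_evo(self.DECAY, self._plan(sigma=100.0), 1e6)
        assert err.value.achievable_snr < 1e6

    def test_planning_curve_monotone_in_time(self):
        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        df = planning_curve(self.DECAY, self._plan(), 50.0, times)
        tau = df["tau_evo_ns"].dropna().to_numpy()
        assert np.all(np.diff(tau) >= 0)
        both = df.dropna()
        assert np.all(both["tau_evo_ns"] <= both["tau_evo_central_ns"])


def _plan(sequence, tau_evo, tau1=400.0, dt=8.0):
    return SequencePlan(sequence=sequence, tau1=tau1, tau_evo=tau_evo,
                        dt=dt)


class TestSelectSequence:
    def test_rule1_longer_tau_evo_prefers_four(self):
        chosen = select_sequence(_plan("four_pulse", 4200.0),
                                 _plan("five_pulse", 4000.0))
        assert chosen.sequence == "four_pulse"
        assert any("rule 1" in m for m in chosen.rationale)

    def test_rule2_similar_amplitude_prefers_four(self):
        chosen = select_sequence(_plan("four_pulse", 4000.0),
                                 _plan("five_pulse", 4000.0),
                                 amplitude_ratio_four_to_five=0.95)
        assert chosen.sequence == "four_pulse"
        assert any("rule 2" in m for m in chosen.rationale)

    def test_much_lower_amplitude_keeps_five(self):
        chosen = select_sequence(_plan("four_pulse", 4000.0),
                                 _plan("five_pulse", 4000.0),
                                 amplitude_ratio_four_to_five=0.5)
        assert chosen.sequence == "five_pulse"

    def test_rule3_needs_roi(self):
        from deerloop.deer_analysis import ROI
        roi = ROI(mean=4.0, sigma=0.4, low=3.2, high=4.8, alpha=2.0)
        kw = dict(amplitude_ratio_four_to_five=0.5,
                  mean_dipolar_freq_mhz=2.0)
        # 1/tau1 = 1/2150 ns = 0.465 MHz; ratio 4.3 > factor 2 -> five
        five = _plan("five_pulse", 4000.0, tau1=2150.0)
        assert select_sequence(_plan("four_pulse", 4000.0), five,
                               roi=None, **kw).sequence == "five_pulse"
        # similar dipolar frequency -> rule 3 fires only with an ROI
        kw["mean_dipolar_freq_mhz"] = 0.5
        chosen = select_sequence(_plan("four_pulse", 4000.0), five,
                                 roi=roi, **kw)
        assert chosen.sequence == "four_pulse"
        assert any("rule 3" in m for m in chosen.rationale)

    def test_fixed_target_skips_rule1(self):
        chosen = select_sequence(_plan("four_pulse", 4200.0),
                                 _plan("five_pulse", 4000.0),
                                 target_tau_evo_fixed=True)
        assert chosen.sequence == "five_pulse"

    def test_exhaustive_rule_truth_table(self):
        from deerloop.deer_analysis import ROI
        roi = ROI(mean=4.0, sigma=0.4, low=3.2, high=4.8, alpha=2.0)
        for longer4 in (True, False):
            for amp_ratio in (0.95, 0.5, None):
                for dd_similar in (True, False, None):
                    four = _plan("four_pulse", 4200.0 if longer4 else 4000.0)
                    five = _plan("five_pulse", 4000.0, tau1=2150.0)
                    kw = {}
                    if amp_ratio is not None:
                        kw["amplitude_ratio_four_to_five"] = amp_ratio
                    if dd_similar is not None:
                        kw["roi"] = roi
                        kw["mean_dipolar_freq_mhz"] = (
                            0.5 if dd_similar else 5.0)
                    chosen = select_sequence(four, five, **kw)
                    expect_four = (longer4 or amp_ratio == 0.95
                                   or dd_similar is True)
                    assert (chosen.sequence == "four_pulse") == expect_four


class TestAssembleDelays:
    def test_five_pulse_carr_purcell_condition(self):
        plan = assemble_delays("five_pulse", 4000.0, 8.0, tau3_ns=300.0)
        assert plan.tau1 == plan.tau2 == pytest.approx(2150.0)
        # the evolution window spans 2 tau - tau3
        assert 2 * plan.tau1 - plan.tau3 == pytest.approx(4000.0)

    def test_time_axis_starts_at_minus_tmin(self):
        plan = assemble_delays("five_pulse", 2000.0, 8.0, t_min_ns=150.0)
        t = plan.t_axis()
        assert t[0] == -150.0
        assert np.all(np.diff(t) == 8.0)
        assert t.size == plan.n_points

    def test_four_pulse_uses_ridge_else_400(self):
        with_ridge = assemble_delays("four_pulse", 3000.0, 8.0,
                                     ridge_tau1_ns=620.0)
        assert with_ridge.tau1 == 620.0
        default = assemble_delays("four_pulse", 3000.0, 8.0)
        assert default.tau1 == 400.0
        assert default.tau2 == 3000.0

    def test_chirp_pump_collision_detected(self):
        with pytest.raises(PulseCollisionError, match="pump"):
            assemble_delays("five_pulse", 4000.0, 8.0, tau3_ns=140.0,
                            pump_length_ns=256.0,
                            observer_pi_length_ns=12.0)

    def test_invalid_tau_evo(self):
        with pytest.raises(ValueError):
            assemble_delays("five_pulse", -100.0, 8.0)
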