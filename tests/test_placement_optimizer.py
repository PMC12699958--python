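import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deerloop as dl
from deerloop.field_sweep import Spectrum
from deerloop.placement_optimizer import (ExclusiveProbabilities,
                                          PlacementError,
                                          default_pump_menu,
                                          evaluate_placement,
                                          exclusive_probabilities,
                                          modulation_depth,
                                          observer_pulses,
                                          optimise_placement,
                                          pump_bandwidth, pump_length)
from deerloop.pulse_engine import ExcitationProfile, PulseSpec


def _indicator_profile(offsets, lo, hi):
    band = ((offsets >= lo) & (offsets <= hi)).astype(float)
    return ExcitationProfile(offsets=offsets, p_excite=band, p_invert=band)


class TestExclusiveProbabilities:
    OFFS = np.arange(-100.0, 101.0, 1.0)

    def _uniform_spectrum(self):
        return Spectrum(self.OFFS, np.ones_like(self.OFFS), 28.1, 34.0)

    def test_disjoint_half_half_bands(self):
        spec = self._uniform_spectrum()
        pump = _indicator_profile(self.OFFS, -100.0, -0.5)
        obs = _indicator_profile(self.OFFS, 0.5, 100.0)
        p = exclusive_probabilities(pump, obs, spec)
        assert p.p_pump == pytest.approx(0.5, abs=0.01)
        assert p.p_obs == pytest.approx(0.5, abs=0.01)
        assert p.p_none == pytest.approx(0.0, abs=0.02)
        assert modulation_depth(p) == pytest.approx(0.5, abs=0.01)

    def test_zero_pump_profile(self):
        spec = self._uniform_spectrum()
        pump = _indicator_profile(self.OFFS, 1.0, 0.0)  # empty band
        obs = _indicator_profile(self.OFFS, -50.0, 50.0)
        p = exclusive_probabilities(pump, obs, spec)
        assert p.p_pump == 0.0
        assert modulation_depth(p) == 0.0

    def test_full_overlap_kills_both(self):
        spec = self._uniform_spectrum()
        band = _indicator_profile(self.OFFS, -50.0, 50.0)
        p = exclusive_probabilities(band, band, spec)
        assert p.p_pump == pytest.approx(0.0, abs=1e-12)
        assert p.p_obs == pytest.approx(0.0, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        spec = self._uniform_spectrum()
        pump = _indicator_profile(self.OFFS, -50, 0)
        obs = _indicator_profile(self.OFFS[:-1], 0, 50)
        with pytest.raises(ValueError):
            exclusive_probabilities(pump, obs, spec)


class TestModulationDepth:
    @given(st.floats(0.01, 0.49), st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_two_code_paths_agree(self, p_pump, p_obs):
        # lambda via pair fractions equals p_pump/(p_pump+p_obs+p_none)
        p = ExclusiveProbabilities(p_pump=p_pump, p_obs=p_obs)
        lam = modulation_depth(p)
        assert lam == pytest.approx(
            p_pump / (p_pump + p_obs + p.p_none), abs=1e-12)

    @pytest.mark.parametrize("x", [0.1, 0.25, 0.5])
    def test_symmetric_bands_give_lambda_x(self, x):
        p = ExclusiveProbabilities(p_pump=x, p_obs=x)
        assert modulation_depth(p) == pytest.approx(x, abs=1e-12)

    def test_pair_fraction_identities(self):
        p = ExclusiveProbabilities(p_pump=0.3, p_obs=0.2)
        assert p.p_mod == pytest.approx(2 * 0.3 * 0.2)
        assert p.p_unmod == pytest.approx(2 * 0.2 * 0.5 + 2 * 0.2 ** 2)
        assert p.p_pump + p.p_obs + p.p_none == pytest.approx(1.0)


class TestPumpRules:
    @pytest.mark.parametrize("args,expected", [((300, 250, 50), 200),
                                               ((250, 300, 50), 200)])
    def test_pump_bandwidth_formula(self, args, expected):
        assert pump_bandwidth(*args) == expected

    def test_pump_bandwidth_floored_with_warning(self):
        with pytest.warns(UserWarning):
            assert pump_bandwidth(100, 100, 120) == 0.0

    def test_pump_length_caps(self):
        assert pump_length(None, 3000.0) == 256.0
        assert pump_length(None, 2000.0) == 200.0

    def test_broadening_bound_cubic(self):
        long_bound = pump_length(4.0, 1e9, hardware_cap_ns=1e9)
        short_bound = pump_length(2.0, 1e9, hardware_cap_ns=1e9)
        assert long_bound == pytest.approx(8 * short_bound, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pump_length(None, -1.0)
        with pytest.raises(ValueError):
            pump_length(-2.0, 1000.0)


class TestOptimisePlacement:
    def test_empty_menu_rejected(self, nitroxide_spectrum, resonator1):
        obs = observer_pulses(70.0)
        with pytest.raises(PlacementError):
            optimise_placement(nitroxide_spectrum, resonator1, [], obs)

    def test_matches_grid_oracle_within_1pc(self, nitroxide_spectrum,
                                            resonator1):
        # exhaustive 2 MHz grid over (pump, observer) centres vs optimiser
        obs = observer_pulses(70.0, 270.0)
        pump = PulseSpec("rect", obs[1].length, "pi")
        offsets = np.arange(-350.0, 351.0, 2.0)
        cache = {}
        best_grid = 0.0
        wa = nitroxide_spectrum.max_offset
        for wp in np.arange(-200.0, 1.0, 2.0):
            for wo in np.arange(-60.0, 61.0, 2.0):
                f, _ = evaluate_placement(pump, obs, nitroxide_spectrum,
                                          resonator1, wp, wo, wa, offsets,
                                          34.0, cache)
                best_grid = max(best_grid, f)
        placement = optimise_placement(nitroxide_spectrum, resonator1,
                                       [pump], obs, carrier_ghz=34.0,
                                       offsets=offsets,
                                       optimise_omega_a=False)
        assert placement.F >= 0.99 * best_grid

    def test_translation_covariance_flat_transfer(self, nitroxide_spectrum):
        # with a flat transfer function the optimum must translate with
        # the spectrum
        obs = observer_pulses(70.0)
        pump = PulseSpec("rect", obs[1].length, "pi")
        kw = dict(carrier_ghz=None, coarse_step_mhz=20.0, n_starts=2,
                  optimise_omega_a=False)
        base = optimise_placement(nitroxide_spectrum, None, [pump], obs,
                                  **kw)
        shifted = optimise_placement(nitroxide_spectrum.shifted(30.0), None,
                                     [pump], obs, **kw)
        assert shifted.omega_p - base.omega_p == pytest.approx(30.0, abs=2.0)
        assert shifted.omega_o - base.omega_o == pytest.approx(30.0, abs=2.0)
        assert shifted.F == pytest.approx(base.F, rel=0.02)

    def test_chirp_beats_rect_on_high_b1_resonator(self, nitroxide_spectrum,
                                                   resonator1):
        # a high-B1 resonator leaves headroom for swept pump pulses
        obs = observer_pulses(
            70.0, min(resonator1.bandwidth_mhz,
                      nitroxide_spectrum.bandwidth()))
        menu = default_pump_menu(resonator1, nitroxide_spectrum,
                                 obs[0].bandwidth("report"),
                                 rect_length_ns=obs[1].length)
        assert [m.shape for m in menu] == ["rect", "chirp_rect"]
        placement = optimise_placement(nitroxide_spectrum, resonator1, menu,
                                       obs, carrier_ghz=34.0,
                                       coarse_step_mhz=20.0, n_starts=2)
        assert placement.pump_spec.shape == "chirp_rect"

    def test_report_mirrors_pulse_table(self, nitroxide_spectrum,
                                        resonator1):
        import json
        obs = observer_pulses(70.0)
        pump = PulseSpec("rect", obs[1].length, "pi")
        placement = optimise_placement(nitroxide_spectrum, resonator1,
                                       [pump], obs, carrier_ghz=34.0,
                                       coarse_step_mhz=25.0, n_starts=1,
                                       optimise_omega_a=False)
        table = json.loads(placement.report())
        assert {r["pulse"] for r in table["pulses"]} == \
            {"pump", "observer_pi_half", "observer_pi"}
        assert all("length_ns" in r and "bandwidth_MHz" in r
                   for r in table["pulses"])
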