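"""Pump/observer frequency placement by exclusive-excitation maximisation.

A spin contributes dipolar modulation only when one partner is exclusively
observed and the other exclusively pumped. With spectral fractions p_pump,
p_obs, p_none (summing to 1 per spin), pair-level fractions are

    p_mod   = 2 p_pump p_obs
    p_unmod = 2 p_obs p_none + 2 p_obs^2

and the fractional modulation depth is lambda = p_mod / (p_mod + p_unmod).
The placement functional maximised over the pump centre omega_p, observer
centre omega_o and the spectrum-maximum offset omega_A is

    F(omega_p, omega_o, omega_A) = 2 p_pump(omega_p) p_obs(omega_o),

evaluated with simulated excitation profiles filtered by the resonator
transfer function, for each candidate pump pulse in a menu (monochromatic
rectangular and linear-chirp rectangular by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .field_sweep import Spectrum
from .pulse_engine import (ExcitationProfile, InsufficientB1Error, PulseSpec,
                           observer_pulses, simulate_profile)
from .resonator_profile import ResonatorProfile


@dataclass
class ExclusiveProbabilities:
    """Per-spin exclusive excitation fractions and derived pair fractions."""

    p_pump: float
    p_obs: float
    p_none: float = field(init=False)
    p_mod: float = field(init=False)
    p_unmod: float = field(init=False)

    def __post_init__(self) -> None:
        if self.p_pump < -1e-12 or self.p_obs < -1e-12:
            raise ValueError("probabilities must be non-negative")
        self.p_pump = max(self.p_pump, 0.0)
        self.p_obs = max(self.p_obs, 0.0)
        if self.p_pump + self.p_obs > 1.0 + 1e-9:
            raise ValueError("p_pump + p_obs exceeds 1")
        self.p_none = max(1.0 - self.p_pump - self.p_obs, 0.0)
        self.p_mod = 2.0 * self.p_pump * self.p_obs
        self.p_unmod = 2.0 * self.p_obs * self.p_none + 2.0 * self.p_obs ** 2


@dataclass
class PulsePlacement:
    """Result of the placement optimisation for one pump candidate."""

    omega_p: float               # pump centre offset, MHz
    omega_o: float               # observer centre offset, MHz
    omega_A: float               # spectrum-maximum offset, MHz
    F: float                     # functional value 2 p_pump p_obs
    lambda_est: float            # predicted modulation depth
    pump_spec: PulseSpec
    observer_specs: tuple        # (pi/2, pi, pi)
    probabilities: ExclusiveProbabilities | None = None

    def report(self) -> str:
        """JSON summary mirroring a pulse-table row per pulse."""
        rows = []
        for name, spec in [("pump", self.pump_spec),
                           ("observer_pi_half", self.observer_specs[0]),
                           ("observer_pi", self.observer_specs[1])]:
            rows.append({"pulse": name, "type": spec.shape,
                         "length_ns": spec.length,
                         "bandwidth_MHz": spec.bandwidth("report"),
                         "central_frequency_MHz": spec.centre_offset})
        return json.dumps({"F": self.F, "lambda_est": self.lambda_est,
                           "omega_A": self.omega_A, "pulses": rows})


def observer_train_profile(observer_specs, resonator, offsets,
                           carrier_ghz=None) -> ExcitationProfile:
    """Cumulative observer profile: pi/2 transverse conversion times both
    pi inversion factors (the train suppresses sidebands)."""
    half, pi1, pi2 = observer_specs
    p_half = simulate_profile(half, resonator, offsets, carrier_ghz)
    p_pi1 = simulate_profile(pi1, resonator, offsets, carrier_ghz)
    p_pi2 = simulate_profile(pi2, resonator, offsets, carrier_ghz)
    band = p_half.p_excite * p_pi1.p_invert * p_pi2.p_invert
    return ExcitationProfile(offsets=np.asarray(offsets, float),
                             p_excite=band, p_invert=band)


def exclusive_probabilities(pump_profile: ExcitationProfile,
                            obs_profile: ExcitationProfile,
                            spectrum: Spectrum,
                            omega_A: float | None = None
                            ) -> ExclusiveProbabilities:
    """Spectral fractions exclusively pumped / observed.

    Exclusivity is product-minus-overlap: the pump factor is the pump
    inversion probability times (1 - observer band), the observer factor the
    observer band times (1 - pump inversion). Amplitude weighting uses the
    EPR spectrum, optionally translated so its maximum sits at ``omega_A``.
    """
    offsets = pump_profile.offsets
    if offsets.shape != obs_profile.offsets.shape or \
            not np.allclose(offsets, obs_profile.offsets):
        raise ValueError("pump and observer profiles need a common grid")
    if omega_A is None:
        amp = spectrum(offsets)
    else:
        amp = spectrum(offsets - (omega_A - spectrum.max_offset))
    total = np.trapezoid(amp, offsets)
    if total <= 0:
        raise ValueError("spectrum has no weight on the profile grid")
    p_obs_band = obs_profile.p_excite
    p_inv_pump = pump_profile.p_invert
    pbar_pump = p_inv_pump * (1.0 - p_obs_band)
    pbar_obs = p_obs_band * (1.0 - p_inv_pump)
    p_pump = float(np.trapezoid(amp * pbar_pump, offsets) / total)
    p_obs = float(np.trapezoid(amp * pbar_obs, offsets) / total)
    return ExclusiveProbabilities(p_pump=p_pump, p_obs=p_obs)


def modulation_depth(p: ExclusiveProbabilities) -> float:
    """lambda = p_mod / (p_mod + p_unmod); 0 (flagged) when nothing is
    observed. Algebraically equal to p_pump / (p_pump + p_obs + p_none)."""
    denom = p.p_mod + p.p_unmod
    if denom <= 0:
        return 0.0
    return p.p_mod / denom


def pump_bandwidth(bw_resonator: float, bw_spectrum: float,
                   bw_excitation: float) -> float:
    """Sweep bandwidth of the pump: min(resonator, spectrum) - excitation,
    floored at zero (with a warning at the floor)."""
    if min(bw_resonator, bw_spectrum, bw_excitation) < 0:
        raise ValueError("bandwidths must be non-negative")
    bw = min(bw_resonator, bw_spectrum) - bw_excitation
    if bw <= 0:
        import warnings
        warnings.warn("pump bandwidth floored at 0: excitation bandwidth "
                      "consumes the whole available band")
        return 0.0
    return bw


def pump_length(r_min_roi: float | None, tau_evo_ns: float,
                hardware_cap_ns: float = 256.0,
                c_pump: float = 0.25) -> float:
    """Pump-pulse length cap (ns).

    The broadening bound c_pump * r_min^3 / D keeps the pump shorter than
    the dipolar period of the shortest ROI distance; on top of that the
    length is limited to 256 ns or 10% of the dipolar evolution time,
    whichever is less. Without an ROI (initial measurement) only the caps
    apply.
    """
    from .constants import DIPOLAR_CONSTANT_MHZ_NM3 as D
    if tau_evo_ns <= 0 or hardware_cap_ns <= 0:
        raise ValueError("tau_evo and hardware cap must be positive")
    cap = min(hardware_cap_ns, 0.1 * tau_evo_ns)
    if r_min_roi is None:
        return cap
    if r_min_roi <= 0:
        raise ValueError("r_min must be positive")
    broadening_ns = 1e3 * c_pump * r_min_roi ** 3 / D
    return min(cap, broadening_ns)


def default_pump_menu(resonator: ResonatorProfile, spectrum: Spectrum,
                      excitation_bandwidth_mhz: float,
                      rect_length_ns: float,
                      chirp_length_ns: float = 206.0) -> list[PulseSpec]:
    """Monochromatic rect + linear-chirp rect pump candidates.

    Rect/Gaussian pumps share the excitation pulse's bandwidth (length);
    the chirp sweep width follows min(resonator, spectrum) - excitation.
    """
    menu = [PulseSpec("rect", rect_length_ns, "pi")]
    bw = pump_bandwidth(resonator.bandwidth_mhz, spectrum.bandwidth(),
                        excitation_bandwidth_mhz)
    if bw > 0:
        menu.append(PulseSpec("chirp_rect", chirp_length_ns, "pi",
                              sweep_bandwidth=bw))
    return menu


class PlacementError(RuntimeError):
    pass


def _shift_pulse(spec: PulseSpec, centre: float) -> PulseSpec:
    return PulseSpec(spec.shape, spec.length, spec.flip, centre,
                     spec.sweep_bandwidth, spec.amplitude_scale,
                     spec.amplitude_mhz, spec.edge_smoothing)


def evaluate_placement(pump: PulseSpec, observer_specs, spectrum: Spectrum,
                       resonator: ResonatorProfile | None,
                       omega_p: float, omega_o: float, omega_A: float,
                       offsets: np.ndarray, carrier_ghz: float | None,
                       _cache: dict | None = None
                       ) -> tuple[float, ExclusiveProbabilities]:
    """F and the exclusive probabilities for one placement candidate."""
    key_p = ("pump", round(omega_p, 1))
    key_o = ("obs", round(omega_o, 1))
    cache = _cache if _cache is not None else {}
    if key_p not in cache:
        cache[key_p] = simulate_profile(_shift_pulse(pump, round(omega_p, 1)),
                                        resonator, offsets, carrier_ghz)
    if key_o not in cache:
        specs = tuple(_shift_pulse(s, round(omega_o, 1))
                      for s in observer_specs)
        cache[key_o] = observer_train_profile(specs, resonator, offsets,
                                              carrier_ghz)
    probs = exclusive_probabilities(cache[key_p], cache[key_o], spectrum,
                                    omega_A=omega_A)
    return 2.0 * probs.p_pump * probs.p_obs, probs


def optimise_placement(spectrum: Spectrum,
                       resonator: ResonatorProfile | None,
                       pulse_menu: list[PulseSpec],
                       observer_specs,
                       carrier_ghz: float | None = None,
                       offsets: np.ndarray | None = None,
                       coarse_step_mhz: float = 10.0,
                       n_starts: int = 3,
                       optimise_omega_a: bool = True) -> PulsePlacement:
    """Maximise F over (omega_p, omega_o, omega_A) for each pump candidate.

    Multi-start bounded Nelder-Mead seeded on a coarse grid; the menu-wide
    argmax wins, with ties broken toward the earlier (simpler) menu entry.
    ``omega_A`` shifts the spectrum axis (equivalent, through the effective
    gyromagnetic ratio, to moving the static field).
    """
    if not pulse_menu:
        raise PlacementError("empty pulse menu")
    if offsets is None:
        span = max(abs(spectrum.offsets[0]), abs(spectrum.offsets[-1])) + 100
        offsets = np.arange(-span, span + 1.0, 2.0)

    wa0 = spectrum.max_offset
    best: PulsePlacement | None = None
    shortfalls = []
    for pump in pulse_menu:
        try:
            cand = _optimise_candidate(pump, observer_specs, spectrum,
                                       resonator, offsets, carrier_ghz, wa0,
                                       coarse_step_mhz, n_starts,
                                       optimise_omega_a)
        except InsufficientB1Error as err:
            shortfalls.append((pump.shape, err.shortfall_mhz))
            continue
        if best is None or cand.F > best.F * (1.0 + 1e-9):
            best = cand
    if best is None:
        raise PlacementError(f"all pump candidates infeasible: {shortfalls}")
    return best


def _optimise_candidate(pump, observer_specs, spectrum, resonator, offsets,
                        carrier_ghz, wa0, coarse_step, n_starts,
                        optimise_omega_a) -> PulsePlacement:
    cache: dict = {}
    span = spectrum.bandwidth() / 2.0 + 60.0
    grid = np.arange(wa0 - span, wa0 + span + 1e-9, coarse_step)

    def f_neg(x):
        wp, wo = x[0], x[1]
        wa = x[2] if optimise_omega_a else wa0
        val, _ = evaluate_placement(pump, observer_specs, spectrum,
                                    resonator, wp, wo, wa, offsets,
                                    carrier_ghz, cache)
        return -val

    # coarse grid over (pump, observer) centres at omega_A = spectrum max
    coarse = []
    for wp in grid:
        for wo in grid:
            coarse.append((f_neg([wp, wo, wa0]), wp, wo))
    coarse.sort(key=lambda c: c[0])

    best_val, best_x = np.inf, None
    for _, wp, wo in coarse[:n_starts]:
        x0 = [wp, wo, wa0]
        res = minimize(f_neg, x0, method="Nelder-Mead",
                       options={"xatol": 0.1, "fatol": 1e-8,
                                "maxfev": 400})
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    wp, wo = float(best_x[0]), float(best_x[1])
    wa = float(best_x[2]) if optimise_omega_a else wa0
    f_val, probs = evaluate_placement(pump, observer_specs, spectrum,
                                      resonator, wp, wo, wa, offsets,
                                      carrier_ghz, cache)
    return PulsePlacement(
        omega_p=wp, omega_o=wo, omega_A=wa, F=f_val,
        lambda_est=modulation_depth(probs),
        pump_spec=_shift_pulse(pump, wp),
        observer_specs=tuple(_shift_pulse(s, wo) for s in observer_specs),
        probabilities=probs)


__all__ = [
    "ExclusiveProbabilities", "PulsePlacement", "PlacementError",
    "exclusive_probabilities", "modulation_depth", "pump_bandwidth",
    "pump_length", "default_pump_menu", "observer_train_profile",
    "observer_pulses", "evaluate_placement", "optimise_placement",
]
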