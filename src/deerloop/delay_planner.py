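"""Time-domain planning: time step, evolution time, delays, sequence choice.

The pump-pulse time step converts to a minimum reliably detectable distance
through a Nyquist rule with an 85% safety margin and a factor 4 (the Pake
pattern has shoulders at twice the perpendicular dipolar frequency):

    r_min = (4 D dt / 0.85)^(1/3),   D = 52.04 MHz nm^3.

The target dipolar evolution time follows the rule of thumb
tau_evo = T_ref (r_max / L_type)^3 with L_type graded by the desired
information content (presence 6 nm, mean 5 nm, width 4 nm, shape 3 nm).
The achievable tau_evo for a measurement time T comes from the total-SNR
model

    SNR(tau_evo) = (V~(tau_evo) / sigma) sqrt(T / (SRT N_points(tau_evo))),

whose largest root at the required SNR = MNR / lambda (evaluated on the
lower decay band V~ - sigma) is taken. Four- vs five-pulse selection and
centre-to-centre delay assembly follow explicit decision rules recorded in
a human-readable trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (DIPOLAR_CONSTANT_MHZ_NM3, NYQUIST_SAFETY,
                        PAKE_SHOULDER_FACTOR)
from .relaxation_analysis import DecayFit

#: tau_evo rule-of-thumb reference length scales per information level, nm
L_TYPE_NM = {"presence": 6.0, "mean": 5.0, "width": 4.0, "shape": 3.0}
#: reference evolution time of the rule of thumb, us
TAU_EVO_REFERENCE_US = 2.0
#: default phase-cycle steps per sequence
PHASE_STEPS = {"four_pulse": 8, "five_pulse": 16}


class SplitMeasurementError(RuntimeError):
    """Raised when no admissible time step fits the AWG memory limit."""


@dataclass
class TimeStepPlan:
    dt: float                    # ns
    r_min_detectable: float      # nm
    awg_limited: bool = False
    warnings: list = field(default_factory=list)


@dataclass
class SequencePlan:
    sequence: str                # four_pulse | five_pulse
    tau1: float = 400.0          # ns
    tau2: float = 0.0            # ns
    tau3: float = 300.0          # ns (five-pulse only)
    tau_evo: float = 0.0         # ns
    t_min: float = 150.0         # ns
    dt: float = 8.0              # ns
    predicted_snr: float = 0.0
    predicted_mnr: float = 0.0
    rationale: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence not in ("four_pulse", "five_pulse"):
            raise ValueError(f"unknown sequence {self.sequence!r}")

    @property
    def n_points(self) -> int:
        return max(int(round(self.tau_evo / self.dt)), 1)

    def t_axis(self) -> np.ndarray:
        """Pump positions (ns) relative to the main-pathway refocusing
        point: from -t_min in steps of dt across the evolution window."""
        return -self.t_min + self.dt * np.arange(self.n_points)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("sequence", "tau1", "tau2", "tau3", "tau_evo", "t_min", "dt",
              "predicted_snr", "predicted_mnr", "rationale")}
        return json.dumps(d)


@dataclass
class SensitivityPlan:
    """Bookkeeping for the total-SNR planning model."""

    T_h: float                   # total measurement time, hours
    srt_ms: float                # shot repetition time
    dt_ns: float                 # time step (uniform sampling)
    sigma: float                 # noise std per single acquisition
    decay_sigma: float = 0.0     # noise std of the measured decay trace,
    #                              used for the V~ +/- sigma planning bands

    def n_points(self, tau_evo_ns) -> np.ndarray:
        return np.maximum(np.asarray(tau_evo_ns, float) / self.dt_ns, 1.0)


def r_min_for_dt(dt_ns: float) -> float:
    """Minimum detectable distance (nm) for a pump time step (ns)."""
    return float((PAKE_SHOULDER_FACTOR * DIPOLAR_CONSTANT_MHZ_NM3
                  * dt_ns * 1e-3 / NYQUIST_SAFETY) ** (1.0 / 3.0))


def choose_time_step(awg_point_limit: int | None = None,
                     expect_short: bool = False,
                     tau_evo_ns: float | None = None,
                     dt_default_ns: float = 8.0) -> TimeStepPlan:
    """Pick the pump time step.

    dt = 8 ns by default (r_min 1.25 nm); escalates in hardware doublings
    while the per-scan point count exceeds the AWG memory limit. dt > 16 ns
    (r_min 1.58 nm) risks short-distance distortions and warns (hard warning
    when short distances are expected); dt > 32 ns is refused in favour of a
    split measurement.
    """
    dt = dt_default_ns
    warnings_list: list[str] = []
    limited = False
    if awg_point_limit is not None and tau_evo_ns is not None:
        while tau_evo_ns / dt > awg_point_limit:
            dt *= 2.0
            limited = True
            if dt > 32.0:
                raise SplitMeasurementError(
                    "AWG memory limit requires dt > 32 ns; split the "
                    "measurement into two ranges and fit globally")
    r_min = r_min_for_dt(dt)
    if dt > 16.0:
        msg = (f"dt = {dt:.0f} ns risks distortion of distances below "
               f"{r_min:.2f} nm")
        if expect_short:
            msg = "SHORT DISTANCES EXPECTED: " + msg
        warnings_list.append(msg)
    return TimeStepPlan(dt=dt, r_min_detectable=r_min, awg_limited=limited,
                        warnings=warnings_list)


def tau_evo_for_target(r_max_nm: float, info_level: str = "mean",
                       t_ref_us: float = TAU_EVO_REFERENCE_US) -> float:
    """Rule-of-thumb evolution time (ns): T_ref (r_max / L_type)^3."""
    if r_max_nm <= 0:
        raise ValueError("r_max must be positive")
    L = L_TYPE_NM[info_level]
    return float(t_ref_us * 1e3 * (r_max_nm / L) ** 3)


def required_snr(target_mnr: float, lambda_est: float) -> float:
    """SNR needed for a target modulation-to-noise ratio: MNR / lambda."""
    if lambda_est <= 0:
        raise ValueError("modulation absent (lambda = 0); plan against a "
                         "target SNR instead")
    return target_mnr / lambda_est


def snr_curve(decay: DecayFit, plan: SensitivityPlan,
              band: str = "central"):
    """SNR(tau_evo_ns) evaluator under the total-time budget.

    ``band`` selects the central estimate or the lower/upper decay bands
    V~ -/+ sigma used to make the planned tau_evo conservative.
    """
    shift = {"central": 0.0, "lower": -plan.decay_sigma,
             "upper": +plan.decay_sigma}[band]
    t_total_srt = plan.T_h * 3600.0 / (plan.srt_ms * 1e-3)

    def snr(tau_evo_ns):
        tau = np.asarray(tau_evo_ns, dtype=float)
        v = np.clip(decay.v_norm(tau * 1e-3) + shift, 0.0, None)
        return (v / plan.sigma) * np.sqrt(t_total_srt / plan.n_points(tau))

    return snr


def optimal_tau_evo(decay: DecayFit, plan: SensitivityPlan,
                    target_snr: float,
                    tau_bounds_ns: tuple[float, float] = (200.0, 20000.0),
                    use_lower_band: bool = True) -> float:
    """Largest tau_evo (ns) whose planned SNR still meets the target.

    Evaluated on the lower decay band by default; grid bracketing on the
    dt raster followed by bisection. Raises if even the shortest allowed
    tau_evo misses the target, reporting the achievable SNR there.
    """
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    snr = snr_curve(decay, plan, "lower" if use_lower_band else "central")
    taus = np.arange(tau_bounds_ns[0], tau_bounds_ns[1] + plan.dt_ns,
                     plan.dt_ns)
    ok = snr(taus) >= target_snr
    if not ok.any():
        raise TargetUnreachableError(
            target_snr, float(snr(taus[0])), taus[0])
    if ok[-1]:
        return float(taus[-1])       # sigma -> 0 limit: bound is binding
    i = int(np.max(np.nonzero(ok)[0]))   # largest crossing
    lo, hi = taus[i], taus[i + 1]
    from scipy.optimize import brentq
    f = lambda x: snr(x) - target_snr
    if f(lo) == 0:
        return float(lo)
    try:
        return float(brentq(f, lo, hi, xtol=0.5))
    except ValueError:
        return float(lo)


class TargetUnreachableError(RuntimeError):
    def __init__(self, target_snr, achievable_snr, at_tau_ns):
        self.target_snr = target_snr
        self.achievable_snr = achievable_snr
        self.at_tau_ns = at_tau_ns
        super().__init__(
            f"SNR target {target_snr:.1f} unreachable: only "
            f"{achievable_snr:.1f} at tau_evo = {at_tau_ns:.0f} ns")


def planning_curve(decay: DecayFit, plan: SensitivityPlan,
                   target_snr: float, times_h: np.ndarray) -> pd.DataFrame:
    """tau_evo as a function of measurement time with decay bands."""
    rows = []
    for T in np.asarray(times_h, dtype=float):
        p = SensitivityPlan(T_h=T, srt_ms=plan.srt_ms, dt_ns=plan.dt_ns,
                            sigma=plan.sigma,
                            decay_sigma=plan.decay_sigma)
        row = {"T_h": T}
        for name, lower in (("tau_evo_ns", True), ("tau_evo_central_ns",
                                                   False)):
            try:
                row[name] = optimal_tau_evo(decay, p, target_snr,
                                            use_lower_band=lower)
            except TargetUnreachableError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def select_sequence(four: SequencePlan, five: SequencePlan,
                    roi=None, target_tau_evo_fixed: bool = False,
                    amplitude_ratio_four_to_five: float | None = None,
                    mean_dipolar_freq_mhz: float | None = None,
                    similar_amplitude_tol: float = 0.10,
                    omega_dd_similarity_factor: float = 2.0) -> SequencePlan:
    """Choose four- vs five-pulse DEER by three explicit preference rules.

    Four-pulse is preferred when (1) it reaches a longer tau_evo in the same
    time, (2) its signal amplitude at the same tau_evo is within 10% of the
    five-pulse one, or (3) the mean dipolar frequency is similar to 1/tau1
    (pathway overlap makes the five-pulse fit fragile; requires a known
    ROI). With a fixed target tau_evo only rules 2-3 apply.
    """
    trace = []
    pick_four = False
    if not target_tau_evo_fixed and four.tau_evo > five.tau_evo:
        pick_four = True
        trace.append(f"rule 1: four-pulse reaches tau_evo {four.tau_evo:.0f}"
                     f" ns > five-pulse {five.tau_evo:.0f} ns")
    if not pick_four and amplitude_ratio_four_to_five is not None \
            and abs(four.tau_evo - five.tau_evo) <= 0.5 * four.dt + 1e-9:
        if amplitude_ratio_four_to_five >= 1.0 - similar_amplitude_tol:
            pick_four = True
            trace.append("rule 2: four-pulse amplitude within "
                         f"{similar_amplitude_tol:.0%} of five-pulse at the "
                         "same tau_evo")
    if not pick_four and roi is not None \
            and mean_dipolar_freq_mhz is not None:
        inv_tau1_mhz = 1e3 / five.tau1 if five.tau1 > 0 else np.inf
        ratio = mean_dipolar_freq_mhz / inv_tau1_mhz
        if 1.0 / omega_dd_similarity_factor <= ratio \
                <= omega_dd_similarity_factor:
            pick_four = True
            trace.append("rule 3: mean dipolar frequency "
                         f"{mean_dipolar_freq_mhz:.2f} MHz similar to "
                         f"1/tau1 = {inv_tau1_mhz:.2f} MHz")
    chosen = four if pick_four else five
    if not pick_four:
        trace.append("five-pulse retained: no four-pulse preference rule "
                     "fired")
    chosen.rationale = chosen.rationale + trace
    return chosen


class PulseCollisionError(RuntimeError):
    pass


def assemble_delays(sequence: str, tau_evo_ns: float, dt_ns: float,
                    t_min_ns: float = 150.0, tau3_ns: float = 300.0,
                    ridge_tau1_ns: float | None = None,
                    pump_length_ns: float = 0.0,
                    observer_pi_length_ns: float = 0.0,
                    separation_guard_ns: float = 16.0) -> SequencePlan:
    """Centre-to-centre delay assembly.

    Five-pulse: tau1 = tau2 = (tau_evo + tau3)/2 (Carr-Purcell-2 condition;
    the dominant pathway refocuses at t = tau3, so 2 tau - tau3 spans the
    requested window). Four-pulse: tau2 = tau_evo, tau1 from the 2D ridge
    when available else 400 ns. The pump sweep starts t_min before the main
    refocusing point in steps of dt. Swept pump pulses are checked for
    collision with the neighbouring observer pulse.
    """
    if tau_evo_ns <= 0:
        raise ValueError("tau_evo must be positive")
    if sequence == "five_pulse":
        tau = (tau_evo_ns + tau3_ns) / 2.0
        plan = SequencePlan(sequence=sequence, tau1=tau, tau2=tau,
                            tau3=tau3_ns, tau_evo=tau_evo_ns,
                            t_min=t_min_ns, dt=dt_ns)
        # static pump at tau3 before the first refocusing pulse must clear it
        min_sep = tau3_ns
    else:
        tau1 = ridge_tau1_ns if ridge_tau1_ns is not None else 400.0
        plan = SequencePlan(sequence=sequence, tau1=tau1, tau2=tau_evo_ns,
                            tau3=0.0, tau_evo=tau_evo_ns, t_min=t_min_ns,
                            dt=dt_ns)
        min_sep = t_min_ns
    half_span = (pump_length_ns + observer_pi_length_ns) / 2.0
    if pump_length_ns > 0 and min_sep < half_span + separation_guard_ns:
        raise PulseCollisionError(
            f"pump pulse ({pump_length_ns:.0f} ns) collides with the "
            f"observer pi pulse ({observer_pi_length_ns:.0f} ns): "
            f"separation {min_sep:.0f} ns < "
            f"{half_span + separation_guard_ns:.0f} ns required")
    plan.rationale.append(
        f"{sequence}: tau1={plan.tau1:.0f} ns, tau2={plan.tau2:.0f} ns"
        + (f", tau3={plan.tau3:.0f} ns" if sequence == "five_pulse" else "")
        + f", t_min={t_min_ns:.0f} ns, dt={dt_ns:.0f} ns")
    return plan
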