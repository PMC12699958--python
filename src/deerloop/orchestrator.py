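"""Closed-loop protocol driver.

Runs the full automated DEER sequence against the virtual spectrometer:
field sweep -> SRT optimisation -> resonator profile (with one re-centre
loop) -> pulse placement -> relaxation -> delay planning -> initial DEER
with MNR monitoring -> ROI -> re-optimisation (including the pump-length
broadening recheck) -> final DEER until the MNR target is met or the time
budget is exhausted. Every decision is appended to a human-readable log;
re-running with the same configuration and seed reproduces the log
verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import (deer_analysis, delay_planner, field_sweep, instrument_sim,
               placement_optimizer, relaxation_analysis, resonator_profile,
               srt_optimizer)
from .constants import GAMMA_NITROXIDE_MHZ_PER_MT
from .deer_analysis import DEERTrace
from .delay_planner import PHASE_STEPS, SensitivityPlan

STAGES = ("sample_insertion", "field_sweep", "srt_optimisation",
          "resonator_profile", "pulse_optimisation", "relaxation",
          "delay_planning", "initial_deer", "roi", "reoptimise",
          "final_deer", "done")


@dataclass
class ProtocolConfig:
    """Operator inputs and protocol defaults."""

    max_time_h: float = 24.0
    temperature_k: float = 50.0
    labelling_efficiency_est: float = 1.0
    mnr_target: float = 150.0
    mnr_initial_target: float = 20.0
    mnr_continue_floor: float = 10.0
    initial_time_budget_h: float = 2.0
    initial_time_cap_h: float = 4.0
    resonator_centre_guess_ghz: float = 34.05
    mode: str = "fully_automated"            # or "advanced"
    sequence_override: str | None = None     # advanced: four/five_pulse
    # hardware / protocol knobs
    dt_ns: float = 8.0
    awg_point_limit: int | None = None
    t_min_ns: float = 150.0
    tau3_ns: float = 300.0
    srt_mode: str = "recovery_fraction"
    srt_fraction: float = 0.8
    srt_min_ms: float = 0.0
    shots: int = 20
    info_level_final: str = "shape"
    roi_alpha: float = 2.0
    n_boot_final: int = 20
    default_srt_ms: float = 3.0              # before the SRT scan exists
    placement_coarse_step_mhz: float = 20.0
    tau_evo_bounds_ns: tuple = (400.0, 12000.0)

    def __post_init__(self) -> None:
        if min(self.max_time_h, self.initial_time_budget_h,
               self.initial_time_cap_h) <= 0:
            raise ValueError("time budgets must be positive")
        if not self.mnr_initial_target < self.mnr_target:
            raise ValueError("initial MNR target must be below the final "
                             "target")


@dataclass
class ProtocolState:
    stage: str = "sample_insertion"
    artefacts: dict = dc_field(default_factory=dict)
    decision_log: list = dc_field(default_factory=list)
    elapsed_h: float = 0.0
    warnings: list = dc_field(default_factory=list)

    def log(self, msg: str) -> None:
        self.decision_log.append(msg)

    def advance(self, stage: str) -> None:
        self.stage = stage

    def report(self) -> str:
        lines = [f"# Protocol report", f"final stage: {self.stage}",
                 f"simulated elapsed time: {self.elapsed_h:.2f} h", "",
                 "## Decision log"]
        lines += [f"- {m}" for m in self.decision_log]
        return "\n".join(lines)

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            for msg in self.decision_log:
                fh.write(json.dumps({"message": msg}) + "\n")


class _SeedStream:
    def __init__(self, seed: int):
        self._state = np.random.SeedSequence(seed).generate_state(
            4096, dtype=np.uint32)
        self._i = 0

    def next(self) -> int:
        s = int(self._state[self._i]) & 0x7FFFFFFF
        self._i += 1
        return s


def monitor_mnr(trace_stream, mnr_target: float, budget_h: float,
                scan_time_h: float, fit_func, state: ProtocolState | None
                = None):
    """Per-scan MNR monitoring with geometric fit intervals.

    ``trace_stream(n_scans)`` returns the cumulative trace after n scans;
    fitting happens after scans 1, 2, 4, 8, ... (a simple two-pathway fit
    concurrent with acquisition). Returns (decision, n_scans, last_fit)
    where decision is ``stop_target_reached`` or ``stop_time``.
    """
    max_scans = int(budget_h / scan_time_h) if scan_time_h > 0 else 0
    if max_scans < 1:
        return "stop_time", 0, None
    checkpoints = []
    k = 1
    while k < max_scans:
        checkpoints.append(k)
        k *= 2
    checkpoints.append(max_scans)
    last_fit = None
    for n in checkpoints:
        trace = trace_stream(n)
        try:
            last_fit = fit_func(trace)
        except Exception as err:   # fit failure: keep scanning
            if state is not None:
                state.warnings.append(f"MNR fit failed at scan {n}: {err}")
            continue
        mnr = deer_analysis.compute_mnr(last_fit)
        if mnr >= mnr_target:
            return "stop_target_reached", n, last_fit
    return "stop_time", max_scans, last_fit


def run_protocol(config: ProtocolConfig,
                 sample: instrument_sim.GroundTruthSample,
                 seed: int) -> ProtocolState:
    """Execute the whole closed-loop protocol on the virtual spectrometer."""
    seeds = _SeedStream(seed)
    state = ProtocolState()
    art = state.artefacts

    # ------------------------------------------------------------------ 1
    state.log(f"sample inserted; temperature {config.temperature_k:.0f} K, "
              f"budget {config.max_time_h:.1f} h, mode {config.mode}")
    if abs(config.temperature_k - 50.0) > 15.0:
        state.warnings.append("temperature far from the 50 K optimum for "
                              "nitroxide DEER")
    carrier = config.resonator_centre_guess_ghz

    # ------------------------------------------------------------------ 2
    state.advance("field_sweep")
    spectrum = _measure_spectrum(config, sample, carrier, seeds, state)
    art["spectrum"] = spectrum

    # ------------------------------------------------------------------ 3
    state.advance("srt_optimisation")
    srt_ms, recovery = _optimise_srt(config, sample, seeds, state)
    art["recovery_fit"] = recovery
    art["srt_ms"] = srt_ms

    # ------------------------------------------------------------------ 4
    state.advance("resonator_profile")
    profile, carrier, spectrum = _measure_profile(
        config, sample, carrier, spectrum, srt_ms, seeds, state)
    art["resonator"] = profile
    art["spectrum"] = spectrum

    # ------------------------------------------------------------------ 5
    state.advance("pulse_optimisation")
    placement = _optimise_pulses(config, spectrum, profile, state)
    art["placement"] = placement
    lambda_eff = placement.lambda_est * config.labelling_efficiency_est
    state.log(f"predicted modulation depth {placement.lambda_est:.3f}; "
              f"scaled by labelling estimate "
              f"{config.labelling_efficiency_est:.2f} -> {lambda_eff:.3f}")

    # ------------------------------------------------------------------ 6
    state.advance("relaxation")
    relax = _measure_relaxation(config, sample, srt_ms, seeds, state)
    art.update(relax)

    # ------------------------------------------------------------------ 7
    state.advance("delay_planning")
    plan = _plan_initial(config, relax, srt_ms, lambda_eff, placement,
                         state)
    art["initial_plan"] = plan

    # ------------------------------------------------------------------ 8
    state.advance("initial_deer")
    dist0, retried = _run_initial_deer(config, sample, plan, placement,
                                       lambda_eff, relax, srt_ms, seeds,
                                       state)
    if dist0 is None:
        state.log("initial DEER yielded no usable modulation; protocol "
                  "aborted with warnings")
        state.advance("done")
        return state
    art["initial_distribution"] = dist0

    # ------------------------------------------------------------------ 9
    state.advance("roi")
    roi = deer_analysis.roi_from_distribution(dist0, alpha=config.roi_alpha)
    art["roi"] = roi
    state.log(f"ROI from Gaussian fit: mean {roi.mean:.2f} nm, sigma "
              f"{roi.sigma:.2f} nm -> [{roi.low:.2f}, {roi.high:.2f}] nm"
              + (" (poor Gaussian fit)" if roi.poor_fit else ""))

    # ----------------------------------------------------------------- 10
    state.advance("reoptimise")
    final_plan = _reoptimise(config, relax, srt_ms, dist0, roi, placement,
                             state)
    art["final_plan"] = final_plan

    # ----------------------------------------------------------------- 11
    state.advance("final_deer")
    dist = _run_final_deer(config, sample, final_plan, placement, dist0,
                           roi, seeds, state)
    art["final_distribution"] = dist
    art["final_roi"] = deer_analysis.roi_from_distribution(
        dist, alpha=config.roi_alpha)
    state.advance("done")
    return state


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _acq_per_point(config, sequence: str) -> int:
    return config.shots * PHASE_STEPS[sequence]

def _measure_spectrum(config, sample, carrier, seeds, state):
    b0 = carrier * 1e3 / GAMMA_NITROXIDE_MHZ_PER_MT
    fields = np.linspace(b0 - 12.0, b0 + 12.0, 241)
    req = instrument_sim.ExperimentRequest(
        "EDFS", axes={"field_mT": fields}, shots=512,
        params={"carrier_GHz": carrier})
    rec = instrument_sim.run_experiment(req, sample, seeds.next())
    state.elapsed_h += fields.size * req.shots * config.default_srt_ms \
        * 1e-3 / 3600.0
    spectrum = field_sweep.process_edfs(fields, rec.data, carrier)
    state.log(f"field sweep at {carrier:.3f} GHz: maximum at "
              f"{spectrum.field_at_max:.2f} mT, gamma_eff "
              f"{spectrum.gamma_eff:.4f} MHz/mT")
    return spectrum


def _optimise_srt(config, sample, seeds, state):
    srt_axis = np.geomspace(0.2, 12.0, 24)
    req = instrument_sim.ExperimentRequest(
        "SRT_SCAN", axes={"srt_ms": srt_axis}, shots=128)
    rec = instrument_sim.run_experiment(req, sample, seeds.next())
    state.elapsed_h += float(np.sum(srt_axis)) * req.shots * 1e-3 / 3600.0
    fit = srt_optimizer.fit_recovery(srt_axis, rec.data)
    if not fit.converged:
        state.warnings.append("SRT recovery fit did not converge; using "
                              "default SRT")
        return config.default_srt_ms, fit
    srt = srt_optimizer.choose_srt(fit, mode=config.srt_mode,
                                   fraction=config.srt_fraction,
                                   srt_min_ms=config.srt_min_ms)
    state.log(f"SRT scan: T1 {fit.T1:.2f} ms, xi {fit.xi:.2f}; "
              f"{config.srt_fraction:.0%} recovery -> SRT {srt:.2f} ms")
    return srt, fit


def _measure_profile(config, sample, carrier, spectrum, srt_ms, seeds,
                     state):
    centre = carrier
    for attempt in range(2):          # at most one re-centre loop
        freqs = np.arange(centre - 0.15, centre + 0.15 + 1e-9, 0.025)
        tp = np.arange(2.0, 130.0, 2.0)
        req = instrument_sim.ExperimentRequest(
            "NUTATION_2D", axes={"freq_GHz": freqs, "pulse_ns": tp},
            shots=64)
        rec = instrument_sim.run_experiment(req, sample, seeds.next())
        state.elapsed_h += freqs.size * tp.size * req.shots * srt_ms \
            * 1e-3 / 3600.0
        points = resonator_profile.extract_profile(freqs, tp, rec.data)
        profile = resonator_profile.fit_profile(points)
        n_acc = sum(1 for _, f in points if f.accepted)
        state.log(f"resonator profile: omega_c {profile.omega_c:.3f} GHz, "
                  f"Q {profile.q_factor:.0f}, nu1max "
                  f"{profile.nu1_max:.1f} MHz ({n_acc}/{len(points)} "
                  "nutation fits accepted)")
        if not resonator_profile.needs_recentre(profile, centre) \
                or attempt == 1:
            break
        state.log(f"fitted centre differs from {centre:.3f} GHz by more "
                  "than 100 MHz: repeating profile and field sweep at the "
                  f"new centre {profile.omega_c:.3f} GHz")
        centre = profile.omega_c
        spectrum = _measure_spectrum(config, sample, centre, seeds, state)
    return profile, centre, spectrum


def _optimise_pulses(config, spectrum, profile, state):
    available_bw = min(profile.bandwidth_mhz, spectrum.bandwidth())
    observer = placement_optimizer.observer_pulses(profile.nu1_max,
                                                   available_bw)
    menu = placement_optimizer.default_pump_menu(
        profile, spectrum, observer[0].bandwidth("report"),
        rect_length_ns=observer[1].length)
    placement = placement_optimizer.optimise_placement(
        spectrum, profile, menu, observer, carrier_ghz=spectrum.carrier,
        coarse_step_mhz=config.placement_coarse_step_mhz, n_starts=2)
    state.log(
        f"pulse placement: {placement.pump_spec.shape} pump "
        f"({placement.pump_spec.length:.0f} ns, "
        f"{placement.pump_spec.sweep_bandwidth:.0f} MHz) at "
        f"{placement.omega_p:.0f} MHz; rectangular observer "
        f"({placement.observer_specs[0].length:.0f} ns) at "
        f"{placement.omega_o:.0f} MHz; F = {placement.F:.4f}")
    return placement


def _measure_relaxation(config, sample, srt_ms, seeds, state):
    out = {}
    preselect = config.sequence_override or "five_pulse"
    if config.sequence_override:
        state.log(f"operator override: sequence fixed to "
                  f"{config.sequence_override}")
    # Carr-Purcell-2 decay with and without the pump pulse
    tau = np.linspace(0.15, 20.0, 120)
    shots = 128
    rec_np = instrument_sim.run_experiment(
        instrument_sim.ExperimentRequest(
            "CP_DECAY", axes={"tau_evo_us": tau}, shots=shots),
        sample, seeds.next())
    rec_p = instrument_sim.run_experiment(
        instrument_sim.ExperimentRequest(
            "CP_DECAY", axes={"tau_evo_us": tau}, shots=shots,
            params={"pump_pulse": True}),
        sample, seeds.next())
    state.elapsed_h += 2 * tau.size * shots * srt_ms * 1e-3 / 3600.0
    fit5 = relaxation_analysis.fit_decay(relaxation_analysis.DecayCurve(
        tau, rec_p.data, kind="cp2", meta={"pump_pulse": True}))
    fit5_np = relaxation_analysis.fit_decay(relaxation_analysis.DecayCurve(
        tau, rec_np.data, kind="cp2"))
    pump_factor = float(np.clip(fit5.A / fit5_np.A, 0.05, 1.0))
    state.log(f"Carr-Purcell decay: Tm {fit5.Tm:.2f} us, xi "
              f"{fit5.xi_m:.2f}; pump-pulse echo reduction factor "
              f"{pump_factor:.2f}")

    if preselect == "four_pulse":
        # optimising four-pulse from the start: full 2D refocused echo
        tau1 = np.arange(0.2, 3.0, 0.2)
        tau2 = np.arange(0.5, 10.0, 0.5)
        rec2d = instrument_sim.run_experiment(
            instrument_sim.ExperimentRequest(
                "REFOCUSED_2D", axes={"tau1_us": tau1, "tau2_us": tau2},
                shots=32, params={"pump_pulse": True}),
            sample, seeds.next())
        state.elapsed_h += tau1.size * tau2.size * 32 * srt_ms * 1e-3 \
            / 3600.0
        ridge = relaxation_analysis.ridge_from_2d(tau1, tau2, rec2d.data)
        out["ridge"] = ridge
        best = ridge.loc[ridge["tau2_us"].sub(2.0).abs().idxmin()]
        out["ridge_tau1_ns"] = float(best["best_tau1_us"]) * 1e3
        state.log("2D refocused echo measured (four-pulse preselected); "
                  f"ridge tau1 near tau2 = 2 us: "
                  f"{out['ridge_tau1_ns']:.0f} ns")
        fit4 = relaxation_analysis.fit_decay(
            relaxation_analysis.DecayCurve(
                tau2, rec2d.data[int(np.argmin(np.abs(tau1 - 0.4)))],
                kind="refocused_2d_slice"))
    else:
        tau2 = np.linspace(0.1, 12.0, 100)
        rec1d = instrument_sim.run_experiment(
            instrument_sim.ExperimentRequest(
                "REFOCUSED_1D", axes={"tau2_us": tau2}, shots=shots,
                params={"tau1_us": 0.4, "pump_pulse": True}),
            sample, seeds.next())
        state.elapsed_h += tau2.size * shots * srt_ms * 1e-3 / 3600.0
        fit4 = relaxation_analysis.fit_decay(relaxation_analysis.DecayCurve(
            tau2, rec1d.data, kind="refocused_1d",
            meta={"tau1_us": 0.4, "pump_pulse": True}))
        state.log("1D refocused echo at tau1 = 400 ns: Tm "
                  f"{fit4.Tm:.2f} us, xi {fit4.xi_m:.2f}")

    # per-acquisition noise estimate from the decay-fit residuals
    sigma_shot = fit5.residual_rms * np.sqrt(shots)
    out.update({"decay_five": fit5, "decay_four": fit4,
                "pump_factor": pump_factor,
                "sigma_shot": float(sigma_shot),
                "preselect": preselect})
    state.log(f"per-acquisition noise estimate {sigma_shot:.2f} "
              "(from decay residuals)")
    return out


def _sensitivity_plan(config, srt_ms, budget_h, sigma_eff, sequence,
                      decay_sigma=0.0):
    return SensitivityPlan(
        T_h=budget_h, srt_ms=srt_ms, dt_ns=config.dt_ns, sigma=sigma_eff,
        decay_sigma=decay_sigma)


def _plan_sequence_tau(config, decay, srt_ms, budget_h, sigma_eff,
                       target_snr, sequence, state):
    decay_sigma = decay.residual_rms / max(decay.A, 1e-9)
    plan = _sensitivity_plan(config, srt_ms, budget_h, sigma_eff, sequence,
                             decay_sigma=decay_sigma)
    try:
        tau = delay_planner.optimal_tau_evo(
            decay, plan, target_snr, tau_bounds_ns=config.tau_evo_bounds_ns)
    except delay_planner.TargetUnreachableError as err:
        state.warnings.append(str(err))
        tau = config.tau_evo_bounds_ns[0]
    return tau


def _plan_initial(config, relax, srt_ms, lambda_eff, placement, state):
    tstep = delay_planner.choose_time_step(
        awg_point_limit=config.awg_point_limit, tau_evo_ns=None,
        dt_default_ns=config.dt_ns)
    state.log(f"time step {tstep.dt:.0f} ns -> minimum detectable "
              f"distance {tstep.r_min_detectable:.2f} nm")
    lam_main = 0.8 * lambda_eff     # dominant-pathway share in five-pulse
    sigma_eff = relax["sigma_shot"] / relax["pump_factor"]
    try:
        snr_needed_5 = delay_planner.required_snr(config.mnr_initial_target,
                                                  lam_main)
        snr_needed_4 = delay_planner.required_snr(config.mnr_initial_target,
                                                  lambda_eff)
    except ValueError:
        state.warnings.append("modulation absent; planning against a "
                              "target SNR of 20")
        snr_needed_5 = snr_needed_4 = 20.0
    tau5 = _plan_sequence_tau(config, relax["decay_five"], srt_ms,
                              config.initial_time_budget_h, sigma_eff,
                              snr_needed_5, "five_pulse", state)
    tau4 = _plan_sequence_tau(config, relax["decay_four"], srt_ms,
                              config.initial_time_budget_h, sigma_eff,
                              snr_needed_4, "four_pulse", state)
    pump_len = placement.pump_spec.length
    plan5 = delay_planner.assemble_delays(
        "five_pulse", tau5, tstep.dt, t_min_ns=config.t_min_ns,
        tau3_ns=config.tau3_ns, pump_length_ns=pump_len,
        observer_pi_length_ns=placement.observer_specs[1].length)
    plan4 = delay_planner.assemble_delays(
        "four_pulse", tau4, tstep.dt, t_min_ns=config.t_min_ns,
        ridge_tau1_ns=relax.get("ridge_tau1_ns"), pump_length_ns=pump_len,
        observer_pi_length_ns=placement.observer_specs[1].length)
    if config.sequence_override:
        chosen = plan4 if config.sequence_override == "four_pulse" \
            else plan5
        chosen.rationale.append("operator override: sequence fixed, "
                                "selection step skipped")
    else:
        chosen = delay_planner.select_sequence(plan4, plan5)
    state.log(f"initial plan: {chosen.sequence}, tau_evo "
              f"{chosen.tau_evo:.0f} ns ({chosen.rationale[-1]})")
    cap = placement_optimizer.pump_length(None, chosen.tau_evo)
    if placement.pump_spec.length > cap:
        state.log(f"pump pulse shortened to {cap:.0f} ns by the "
                  "256 ns / 10% tau_evo cap")
        placement.pump_spec.length = cap
    return chosen


def _deer_stream(config, sample, plan, placement, lambda_eff, seeds):
    """Returns a cumulative-trace factory for MNR monitoring."""
    t_axis = plan.t_axis()
    base_seed = seeds.next()
    secondary = (plan.tau_evo - plan.tau3) / 2.0 \
        if plan.sequence == "five_pulse" else None

    def stream(n_scans: int) -> DEERTrace:
        req = instrument_sim.ExperimentRequest(
            "DEER", axes={"t_ns": t_axis},
            shots=_acq_per_point(config, plan.sequence), scans=n_scans,
            params={"lambda_theory": placement.lambda_est,
                    "sequence": plan.sequence,
                    "tau_evo_ns": plan.tau_evo,
                    "tau1_ns": plan.tau1,
                    **({"secondary_refocus_ns": secondary}
                       if secondary is not None else {})})
        rec = instrument_sim.run_experiment(req, sample,
                                            (base_seed + n_scans)
                                            & 0x7FFFFFFF)
        refocus = [0.0] if plan.sequence == "four_pulse" \
            else [0.0, secondary]
        return DEERTrace(t=t_axis, V=rec.data, sequence=plan.sequence,
                         pathway_refocus_times=refocus, meta=rec.meta)

    return stream


def _scan_time_h(config, plan, srt_ms):
    return plan.n_points * _acq_per_point(config, plan.sequence) \
        * srt_ms * 1e-3 / 3600.0


def _run_initial_deer(config, sample, plan, placement, lambda_eff, relax,
                      srt_ms, seeds, state):
    r_min_floor = delay_planner.r_min_for_dt(plan.dt)
    fit_fast = lambda tr: deer_analysis.fit_deer(
        tr, n_boot=0, r_min_floor=r_min_floor, max_nfev=15)
    for attempt in (1, 2):
        scan_h = _scan_time_h(config, plan, srt_ms)
        stream = _deer_stream(config, sample, plan, placement, lambda_eff,
                              seeds)
        decision, n_scans, fit = monitor_mnr(
            stream, config.mnr_initial_target, config.initial_time_cap_h,
            scan_h, fit_fast, state)
        state.elapsed_h += n_scans * scan_h
        mnr = deer_analysis.compute_mnr(fit) if fit is not None else 0.0
        state.log(f"initial DEER ({plan.sequence}): {n_scans} scans, "
                  f"{decision}, MNR {mnr:.1f}")
        if decision == "stop_target_reached" \
                or mnr >= config.mnr_continue_floor:
            if decision == "stop_time":
                state.log(f"MNR above {config.mnr_continue_floor:.0f}: "
                          "protocol continues despite missing the initial "
                          "target")
            final = deer_analysis.fit_deer(
                stream(n_scans), n_boot=config.n_boot_final,
                r_min_floor=r_min_floor, seed=seeds.next())
            return final, attempt > 1
        if attempt == 1:
            new_est = config.labelling_efficiency_est / 2.0
            state.log(f"MNR {mnr:.1f} below "
                      f"{config.mnr_continue_floor:.0f} at the time cap: "
                      "repeating the initial DEER with labelling "
                      f"estimate lowered to {new_est:.2f}")
            config = _replace_labelling(config, new_est)
            lam_main = 0.8 * placement.lambda_est * new_est
            sigma_eff = relax["sigma_shot"] / relax["pump_factor"]
            try:
                snr_needed = delay_planner.required_snr(
                    config.mnr_initial_target, lam_main)
            except ValueError:
                snr_needed = 20.0
            tau = _plan_sequence_tau(
                config, relax["decay_five" if plan.sequence == "five_pulse"
                              else "decay_four"], srt_ms,
                config.initial_time_budget_h, sigma_eff, snr_needed,
                plan.sequence, state)
            plan = delay_planner.assemble_delays(
                plan.sequence, tau, plan.dt, t_min_ns=plan.t_min,
                tau3_ns=plan.tau3,
                pump_length_ns=placement.pump_spec.length,
                observer_pi_length_ns=placement.observer_specs[1].length)
    return None, True


def _replace_labelling(config: ProtocolConfig, value: float
                       ) -> ProtocolConfig:
    import copy
    cfg = copy.copy(config)
    cfg.labelling_efficiency_est = value
    return cfg


def _reoptimise(config, relax, srt_ms, dist0, roi, placement, state):
    lam_main = max(dist0.lambda_fit, default=0.1)
    sigma_eff = relax["sigma_shot"] / relax["pump_factor"]
    remaining = max(config.max_time_h - state.elapsed_h, 0.1)
    tau_target = delay_planner.tau_evo_for_target(
        roi.high, config.info_level_final)
    try:
        snr_needed = delay_planner.required_snr(config.mnr_target, lam_main)
    except ValueError:
        snr_needed = config.mnr_target
    decay5, decay4 = relax["decay_five"], relax["decay_four"]
    tau5 = _plan_sequence_tau(config, decay5, srt_ms, remaining, sigma_eff,
                              snr_needed, "five_pulse", state)
    tau4 = _plan_sequence_tau(config, decay4, srt_ms, remaining, sigma_eff,
                              snr_needed, "four_pulse", state)
    # never plan below the window needed to pin the mean of the ROI
    # distances, even when that sacrifices MNR
    tau_floor = delay_planner.tau_evo_for_target(roi.high, "mean")
    fixed = False
    if min(tau5, tau4) >= tau_target:
        tau5 = tau4 = tau_target
        fixed = True
        state.log(f"target tau_evo {tau_target:.0f} ns (shape information "
                  "at the ROI upper edge) is achievable in the remaining "
                  "time: fixed for both sequences")
    else:
        if max(tau5, tau4) < tau_floor:
            state.log(f"MNR-limited tau_evo below the mean-distance floor "
                      f"{tau_floor:.0f} ns for the ROI: planning at the "
                      "floor and accepting a lower final MNR")
            tau5 = tau4 = tau_floor
    v5 = float(decay5.v_norm(tau5 * 1e-3) * decay5.A)
    v4 = float(decay4.v_norm(tau4 * 1e-3) * decay4.A)
    plan5 = delay_planner.assemble_delays(
        "five_pulse", tau5, config.dt_ns, t_min_ns=config.t_min_ns,
        tau3_ns=config.tau3_ns,
        pump_length_ns=placement.pump_spec.length,
        observer_pi_length_ns=placement.observer_specs[1].length)
    plan4 = delay_planner.assemble_delays(
        "four_pulse", tau4, config.dt_ns, t_min_ns=config.t_min_ns,
        ridge_tau1_ns=relax.get("ridge_tau1_ns"),
        pump_length_ns=placement.pump_spec.length,
        observer_pi_length_ns=placement.observer_specs[1].length)
    if config.sequence_override:
        chosen = plan4 if config.sequence_override == "four_pulse" \
            else plan5
        chosen.rationale.append("operator override: sequence fixed")
    else:
        chosen = delay_planner.select_sequence(
            plan4, plan5, roi=roi, target_tau_evo_fixed=fixed,
            amplitude_ratio_four_to_five=v4 / v5 if v5 > 0 else None,
            mean_dipolar_freq_mhz=dist0.mean_dipolar_frequency_mhz())
    # pump-length broadening recheck against the ROI lower edge
    cap = placement_optimizer.pump_length(roi.low, chosen.tau_evo)
    if placement.pump_spec.length > cap:
        state.log(f"pump pulse length {placement.pump_spec.length:.0f} ns "
                  f"would broaden distances near {roi.low:.2f} nm: "
                  f"shortened to {cap:.0f} ns and pulses re-set-up")
        placement.pump_spec.length = cap
    state.log(f"final plan: {chosen.sequence}, tau_evo "
              f"{chosen.tau_evo:.0f} ns ({chosen.rationale[-1]})")
    return chosen


def _run_final_deer(config, sample, plan, placement, dist0, roi, seeds,
                    state):
    srt_ms = state.artefacts.get("srt_ms", config.default_srt_ms)
    scan_h = _scan_time_h(config, plan, srt_ms)
    remaining = max(config.max_time_h - state.elapsed_h, scan_h)
    r_min_floor = delay_planner.r_min_for_dt(plan.dt)
    stream = _deer_stream(config, sample, plan, placement, None, seeds)
    fit_fast = lambda tr: deer_analysis.fit_deer(
        tr, n_boot=0, r_min_floor=r_min_floor, max_nfev=15)
    decision, n_scans, _ = monitor_mnr(stream, config.mnr_target,
                                       remaining, scan_h, fit_fast, state)
    state.elapsed_h += n_scans * scan_h
    dist = deer_analysis.fit_deer(stream(n_scans),
                                  n_boot=config.n_boot_final,
                                  r_min_floor=r_min_floor,
                                  seed=seeds.next())
    mnr = deer_analysis.compute_mnr(dist)
    state.log(f"final DEER ({plan.sequence}): {n_scans} scans, {decision}, "
              f"MNR {mnr:.1f}, mean distance {dist.mean_r:.2f} nm")
    return dist
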