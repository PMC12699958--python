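"""Virtual spectrometer for closed-loop protocol runs.

A hidden :class:`GroundTruthSample` answers every setup-experiment request
with noisy synthetic data: an asymmetric three-component pseudo-Voigt
nitroxide line at Q band, stretched-exponential longitudinal recovery and
transverse decays, a Lorentzian resonator mode driving frequency-swept
nutation maps, a global pump-pulse echo-reduction factor, and one- or
two-pathway DEER traces with Gaussian white noise. Noise is deterministic
per record seed and scales as noise_sigma_per_shot / sqrt(shots x scans).

The simulator is deliberately phenomenological: DEER traces come from the
pathway model (kernel times distance distribution), not density-matrix
propagation, and the echo-detected line is a parametric mixture rather than
a spin-Hamiltonian powder average — sufficient to exercise every placement
integral and planning rule of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deer_analysis
from .constants import GAMMA_NITROXIDE_MHZ_PER_MT

KINDS = ("EDFS", "SRT_SCAN", "NUTATION_2D", "CP_DECAY", "REFOCUSED_1D",
         "REFOCUSED_2D", "DEER")


def pseudo_voigt(x_mhz, components) -> np.ndarray:
    """Mixture of pseudo-Voigt lines; components are
    (centre MHz, fwhm MHz, weight, eta)."""
    x = np.asarray(x_mhz, dtype=float)
    out = np.zeros_like(x)
    for centre, fwhm, weight, eta in components:
        hw = fwhm / 2.0
        lor = 1.0 / (1.0 + ((x - centre) / hw) ** 2)
        gau = np.exp(-np.log(2.0) * ((x - centre) / hw) ** 2)
        out += weight * (eta * lor + (1.0 - eta) * gau)
    return out


@dataclass
class GroundTruthSample:
    """Hidden ground truth the protocol never reads directly."""

    # EPR line: pseudo-Voigt components on a frequency-offset axis (MHz
    # from the line maximum's resonance)
    spectrum_components: list = field(default_factory=lambda: [
        (0.0, 18.0, 0.45, 0.3),
        (-50.0, 70.0, 0.35, 0.5),
        (-120.0, 90.0, 0.20, 0.5)])
    gamma_true: float = 28.11          # MHz/mT; differs from the nominal
    T1_true: float = 1.55              # ms
    xi_T1: float = 0.70
    cp_decay: tuple = (1.8, 1.3)       # (Tm us, xi) Carr-Purcell-2
    ref_echo_decay: tuple = (2.2, 1.2)  # (Tm' us, xi') refocused echo
    ridge: tuple | None = None         # (a us, b, w us) planted tau1 ridge
    pump_echo_reduction: float = 0.9   # per pump pulse, (0, 1]
    p_mixture: list = field(default_factory=lambda: [(3.2, 0.45, 0.5),
                                                     (4.0, 0.70, 0.5)])
    labelling_efficiency: float = 0.8
    background_rate: float = 0.05      # 1/us
    noise_sigma_per_shot: float = 1.0
    resonator_true: tuple = (34.0, 70.0, 70.0)   # (GHz, Q, nu1max MHz)
    t2rho_ns: float = 500.0
    r_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 10.0 + 1e-9, 0.05))

    def __post_init__(self) -> None:
        if not 0.0 <= self.labelling_efficiency <= 1.0:
            raise ValueError("labelling_efficiency must lie in [0, 1]")
        if self.noise_sigma_per_shot <= 0:
            raise ValueError("noise_sigma_per_shot must be positive")
        if not 0.0 < self.pump_echo_reduction <= 1.0:
            raise ValueError("pump_echo_reduction must lie in (0, 1]")
        if any(s <= 0 for _, s, _ in self.p_mixture):
            raise ValueError("distance-mixture sigmas must be positive")

    @property
    def p_true(self) -> np.ndarray:
        """Ground-truth P(r), normalised to 1 on r_grid."""
        r = self.r_grid
        p = np.zeros_like(r)
        for mean, sd, wt in self.p_mixture:
            p += wt * np.exp(-0.5 * ((r - mean) / sd) ** 2) / sd
        return p / np.trapezoid(p, r)

    @property
    def mean_distance(self) -> float:
        return float(np.trapezoid(self.r_grid * self.p_true, self.r_grid))

    def nu1_true(self, freq_ghz) -> np.ndarray:
        wc, q, nmax = self.resonator_true
        x = np.asarray(freq_ghz, dtype=float)
        return nmax / np.sqrt(1.0 + (q * (x / wc - wc / x)) ** 2)

    def spectral_amplitude(self, offset_mhz) -> np.ndarray:
        return pseudo_voigt(offset_mhz, self.spectrum_components)

    def v_decay(self, tau_evo_us, sequence: str = "five_pulse",
                tau1_us: float = 0.4) -> np.ndarray:
        """Normalised echo decay at a given evolution time."""
        tau = np.asarray(tau_evo_us, dtype=float)
        if sequence == "five_pulse":
            tm, xi = self.cp_decay
            return np.exp(-((tau / tm) ** xi))
        tm, xi = self.ref_echo_decay
        return np.exp(-((2.0 * (tau1_us + tau) / tm) ** xi))


@dataclass
class ExperimentRequest:
    kind: str
    axes: dict                      # name -> coordinate vector
    shots: int = 10
    scans: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.shots < 1:
            raise ValueError("shots must be >= 1")
        if self.scans < 1:
            raise ValueError("scans must be >= 1")


@dataclass
class ExperimentRecord:
    kind: str
    axes: dict
    data: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        shape = tuple(np.asarray(v).size for v in self.axes.values())
        if tuple(np.shape(self.data)) != shape:
            raise ValueError("axes lengths do not match data shape")

    def write(self, path_prefix: str) -> None:
        """CSV (long format) + JSON sidecar; round-trips via ``read``."""
        import json
        names = list(self.axes)
        grids = np.meshgrid(*[self.axes[n] for n in names], indexing="ij")
        df = pd.DataFrame({n: g.ravel() for n, g in zip(names, grids)})
        df["data"] = np.asarray(self.data).ravel()
        df.to_csv(f"{path_prefix}.csv", index=False)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump({"kind": self.kind,
                       "axis_names": names,
                       "axis_lengths": [int(np.asarray(self.axes[n]).size)
                                        for n in names],
                       "meta": deer_analysis._jsonable(self.meta)}, fh)

    @classmethod
    def read(cls, path_prefix: str) -> "ExperimentRecord":
        import json
        with open(f"{path_prefix}.json") as fh:
            side = json.load(fh)
        df = pd.read_csv(f"{path_prefix}.csv")
        axes = {}
        for n in side["axis_names"]:
            axes[n] = np.unique(df[n].to_numpy())
        shape = tuple(side["axis_lengths"])
        data = df["data"].to_numpy().reshape(shape)
        return cls(kind=side["kind"], axes=axes, data=data,
                   meta=side["meta"])


def _noise_sigma(sample: GroundTruthSample, request: ExperimentRequest
                 ) -> float:
    return sample.noise_sigma_per_shot / np.sqrt(request.shots
                                                 * request.scans)


def run_experiment(request: ExperimentRequest, sample: GroundTruthSample,
                   rng_seed: int) -> ExperimentRecord:
    """Answer one experiment request with a noisy synthetic record."""
    rng = np.random.default_rng(rng_seed)
    sigma = _noise_sigma(sample, request)
    p = request.params
    meta = {"shots": request.shots, "scans": request.scans,
            "seed": int(rng_seed), "noise_sigma": sigma, **p}

    if request.kind == "EDFS":
        field_mt = np.asarray(request.axes["field_mT"], dtype=float)
        carrier = float(p["carrier_GHz"])
        offs = sample.gamma_true * field_mt - carrier * 1e3
        clean = sample.spectral_amplitude(offs)
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "SRT_SCAN":
        srt = np.asarray(request.axes["srt_ms"], dtype=float)
        clean = 1.0 - np.exp(-((srt / sample.T1_true) ** sample.xi_T1))
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "NUTATION_2D":
        freqs = np.asarray(request.axes["freq_GHz"], dtype=float)
        tp = np.asarray(request.axes["pulse_ns"], dtype=float)
        nu1 = sample.nu1_true(freqs)
        clean = (np.cos(2e-3 * np.pi * np.outer(nu1, tp))
                 * np.exp(-tp / sample.t2rho_ns)[None, :])
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "CP_DECAY":
        tau = np.asarray(request.axes["tau_evo_us"], dtype=float)
        tm, xi = sample.cp_decay
        clean = np.exp(-((tau / tm) ** xi))
        if p.get("pump_pulse"):
            clean = clean * sample.pump_echo_reduction
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "REFOCUSED_1D":
        tau2 = np.asarray(request.axes["tau2_us"], dtype=float)
        tau1 = float(p.get("tau1_us", 0.4))
        clean = sample.v_decay(tau2, "four_pulse", tau1_us=tau1)
        if p.get("pump_pulse"):
            clean = clean * sample.pump_echo_reduction
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "REFOCUSED_2D":
        tau1 = np.asarray(request.axes["tau1_us"], dtype=float)
        tau2 = np.asarray(request.axes["tau2_us"], dtype=float)
        tm, xi = sample.ref_echo_decay
        if sample.ridge is not None:
            a, b, w = sample.ridge
            clean = (np.exp(-((2.0 * tau2[None, :] / tm) ** xi))
                     * np.exp(-((tau1[:, None] - a - b * tau2[None, :])
                                / w) ** 2))
        else:
            clean = np.exp(-((2.0 * (tau1[:, None] + tau2[None, :]) / tm)
                             ** xi))
        data = clean + rng.normal(0.0, sigma, clean.shape)

    elif request.kind == "DEER":
        t_ns = np.asarray(request.axes["t_ns"], dtype=float)
        lam_total = (float(p.get("lambda_theory", 0.3))
                     * sample.labelling_efficiency)
        sequence = p.get("sequence", "five_pulse")
        tau_evo_us = float(p.get("tau_evo_ns", t_ns[-1] - t_ns[0])) * 1e-3
        tau1_us = float(p.get("tau1_ns", 400.0)) * 1e-3
        v0 = float(sample.v_decay(tau_evo_us, sequence, tau1_us)
                   * sample.pump_echo_reduction)
        if sequence == "five_pulse":
            t2 = float(p.get("secondary_refocus_ns",
                             (t_ns[-1] + t_ns[0]) / 2.0))
            pathways = [(0.8 * lam_total, 0.0), (0.2 * lam_total, t2)]
        else:
            pathways = [(lam_total, 0.0)]
        trace = deer_analysis.simulate_deer(
            t_ns, sample.r_grid, sample.p_true, pathways,
            background_rate=sample.background_rate, V0=v0,
            noise_sigma=sigma, seed=int(rng.integers(2 ** 31)),
            sequence=sequence, meta=meta)
        return ExperimentRecord(kind="DEER", axes={"t_ns": t_ns},
                                data=trace.V,
                                meta={**meta, "V0_true": v0,
                                      "pathways_true": pathways,
                                      "pathway_refocus_times":
                                          trace.pathway_refocus_times})
    else:  # pragma: no cover - guarded by ExperimentRequest
        raise ValueError(f"unknown experiment kind {request.kind!r}")

    return ExperimentRecord(kind=request.kind, axes=dict(request.axes),
                            data=data, meta=meta)


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

_PRESETS = {
    # protonated matrix: short phase-memory time, broad bimodal distribution
    "protonated-broad": dict(
        T1_true=1.55, xi_T1=0.70, cp_decay=(1.8, 1.3),
        ref_echo_decay=(2.2, 1.2),
        p_mixture=[(3.2, 0.45, 0.5), (4.0, 0.70, 0.5)],
        labelling_efficiency=0.80, background_rate=0.05),
    # deuterated matrix: long coherence, single long distance
    "deuterated-long-distance": dict(
        T1_true=2.0, xi_T1=0.9, cp_decay=(10.0, 1.0),
        ref_echo_decay=(9.0, 1.1),
        p_mixture=[(5.5, 0.60, 1.0)],
        labelling_efficiency=0.85, background_rate=0.03),
    # rigid short pair, narrow line
    "narrow-short": dict(
        T1_true=1.2, xi_T1=0.85, cp_decay=(4.0, 1.1),
        ref_echo_decay=(4.5, 1.1),
        p_mixture=[(3.0, 0.25, 1.0)],
        labelling_efficiency=0.90, background_rate=0.04),
    # poorly labelled sample exercising the initial-DEER retry loop
    "low-labelling": dict(
        T1_true=1.5, xi_T1=0.8, cp_decay=(5.0, 1.0),
        ref_echo_decay=(5.5, 1.1),
        p_mixture=[(4.0, 0.5, 1.0)],
        labelling_efficiency=0.15, background_rate=0.04),
}


def make_fixture_suite(presets=("protonated-broad",
                                "deuterated-long-distance",
                                "narrow-short")) -> dict:
    """Reproducible ground-truth presets spanning short/long coherence and
    narrow/broad distance distributions."""
    if not presets:
        raise ValueError("config must name at least one preset")
    out = {}
    for name in presets:
        if name not in _PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: "
                           f"{sorted(_PRESETS)}")
        out[name] = GroundTruthSample(**_PRESETS[name])
    return out
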