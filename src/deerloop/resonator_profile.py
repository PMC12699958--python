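"""Resonator profile from frequency-swept nutation data.

A 2D nutation experiment (echo amplitude vs pulse length, repeated across
microwave frequencies spanning the resonator mode) is reduced to a 1D profile
nu1(omega) by fitting each transient with a decaying cosine

    A cos(2 pi nu1 t_p) exp(-t_p / T2rho)

or its zeroth-order Bessel analogue A J0(2 pi nu1 t_p) exp(-t_p / T2rho),
valid when the line is much broader than the excitation bandwidth. Traces
with a coefficient of determination R^2 < 0.5 are discarded. The surviving
points are fitted with a detuning Lorentzian

    nu1(omega) = nu1max / sqrt(1 + Q^2 (omega/omega_c - omega_c/omega)^2),

which doubles as the normalised transfer function H(omega) = nu1/nu1max of
the excitation chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import j0

R_SQUARED_GATE = 0.5
RECENTRE_THRESHOLD_MHZ = 100.0


@dataclass
class NutationFit:
    """Single-frequency nutation-trace fit."""

    nu1: float          # MHz
    T2rho: float        # ns
    A: float
    model: str          # "cosine" or "bessel"
    r_squared: float
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = bool(self.r_squared >= R_SQUARED_GATE
                             and self.nu1 >= 0)


@dataclass
class ResonatorProfile:
    """Lorentzian resonator mode; also the transfer function H."""

    omega_c: float      # GHz
    q_factor: float
    nu1_max: float      # MHz
    points: list = field(default_factory=list)  # (freq GHz, nu1 MHz, accepted)
    fit_residual: float = 0.0                   # MHz, rms

    def __post_init__(self) -> None:
        if self.q_factor <= 0:
            raise ValueError("Q must be positive")
        if self.nu1_max <= 0:
            raise ValueError("nu1_max must be positive")

    def nu1(self, freq_ghz) -> np.ndarray:
        """Nutation frequency (MHz) available at an absolute frequency."""
        return lorentzian_mode(np.asarray(freq_ghz, dtype=float),
                               self.omega_c, self.q_factor, self.nu1_max)

    def transfer(self, freq_ghz) -> np.ndarray:
        """Normalised transfer function H in (0, 1]; 1 only at omega_c."""
        return self.nu1(freq_ghz) / self.nu1_max

    @property
    def bandwidth_mhz(self) -> float:
        """Half-power (nu1max/sqrt(2)) full width of the mode, MHz."""
        return self.omega_c * 1e3 / self.q_factor

    def to_json(self) -> str:
        return json.dumps({
            "omega_c": self.omega_c, "q_factor": self.q_factor,
            "nu1_max": self.nu1_max, "fit_residual": self.fit_residual,
            "points": [list(p) for p in self.points]})


def lorentzian_mode(freq_ghz, omega_c, q, nu1max):
    x = np.asarray(freq_ghz, dtype=float)
    detune = x / omega_c - omega_c / x
    return nu1max / np.sqrt(1.0 + (q * detune) ** 2)


def _fft_nu1_guess(t_ns: np.ndarray, signal: np.ndarray) -> float:
    """Legacy estimator: maximum of the FFT magnitude of the transient."""
    n = 4 * t_ns.size
    dt = t_ns[1] - t_ns[0]
    spec = np.abs(np.fft.rfft(signal - signal.mean(), n=n))
    freqs = np.fft.rfftfreq(n, d=dt) * 1e3  # MHz
    return float(freqs[int(np.argmax(spec[1:])) + 1])


def fit_nutation_trace(pulse_lengths_ns: np.ndarray, signal: np.ndarray,
                       model: str = "cosine") -> NutationFit:
    """Fit one nutation transient; initial nu1 from the FFT maximum."""
    t = np.asarray(pulse_lengths_ns, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 16:
        raise ValueError("need at least 16 time points")
    if not np.any(y):
        return NutationFit(nu1=0.0, T2rho=np.inf, A=0.0, model=model,
                           r_squared=0.0)

    nu1_0 = max(_fft_nu1_guess(t, y), 1.0)
    a0 = float(np.max(np.abs(y)))
    if model == "cosine":
        # free phase absorbs the pi/4 asymptotic shift of a Bessel-like
        # transient, keeping the fitted frequency unbiased
        def f(tp, nu1, t2rho, a, phi):
            return a * np.cos(2e-3 * np.pi * nu1 * tp - phi) \
                * np.exp(-tp / t2rho)
        p0 = [nu1_0, 500.0, a0, 0.0]
        bounds = ([0.0, 10.0, 0.0, -np.pi / 2],
                  [2e3, 1e6, 10 * a0 + 1e-12, np.pi / 2])
    else:
        def f(tp, nu1, t2rho, a):
            return a * j0(2e-3 * np.pi * nu1 * tp) * np.exp(-tp / t2rho)
        p0 = [nu1_0, 500.0, a0]
        bounds = ([0.0, 10.0, 0.0], [2e3, 1e6, 10 * a0 + 1e-12])
    try:
        popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return NutationFit(nu1=nu1_0, T2rho=np.inf, A=a0, model=model,
                           r_squared=0.0)
    resid = y - f(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return NutationFit(nu1=float(popt[0]), T2rho=float(popt[1]),
                       A=float(popt[2]), model=model, r_squared=r2)


class ProfileUnfittableError(RuntimeError):
    pass


def extract_profile(freqs_ghz: np.ndarray, pulse_lengths_ns: np.ndarray,
                    data: np.ndarray, model: str = "cosine"
                    ) -> list[tuple[float, NutationFit]]:
    """Reduce a 2D frequency-swept nutation map to per-frequency fits.

    ``data`` has shape (n_freq, n_pulse_lengths). Rejected fits are carried
    but flagged. Frequency spacing above 40 MHz triggers a resolution
    warning; fewer than 3 accepted points make the profile unfittable.
    """
    freqs = np.asarray(freqs_ghz, dtype=float)
    data = np.asarray(data, dtype=float)
    if data.shape != (freqs.size, np.asarray(pulse_lengths_ns).size):
        raise ValueError("data shape does not match axes")
    if freqs.size > 1 and np.max(np.diff(np.sort(freqs))) * 1e3 > 40.0:
        warnings.warn("nutation frequency points spaced more than 40 MHz "
                      "apart; profile resolution may be inadequate")
    fits = [(float(fq), fit_nutation_trace(pulse_lengths_ns, row, model))
            for fq, row in zip(freqs, data)]
    if sum(f.accepted for _, f in fits) < 3:
        raise ProfileUnfittableError("profile unfittable: fewer than 3 "
                                     "accepted nutation fits")
    return fits


def fit_profile(points: list[tuple[float, NutationFit]]) -> ResonatorProfile:
    """Weighted least-squares Lorentzian fit of accepted (freq, nu1) points.

    Falls back to a coarse grid search if the local fit does not converge.
    """
    acc = [(fq, f.nu1) for fq, f in points if f.accepted]
    if len(acc) < 3:
        raise ProfileUnfittableError("need at least 3 accepted points")
    freqs = np.array([a[0] for a in acc])
    nu1s = np.array([a[1] for a in acc])

    wc0 = float(freqs[np.argmax(nu1s)])
    p0 = [wc0, 100.0, float(nu1s.max())]
    bounds = ([freqs.min() - 1.0, 1.0, 1e-3],
              [freqs.max() + 1.0, 1e4, 10 * nu1s.max()])
    try:
        popt, _ = curve_fit(lorentzian_mode, freqs, nu1s, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError:
        # grid-search fallback over (omega_c, Q), nu1max by scaling
        grid_wc = np.linspace(freqs.min(), freqs.max(), 101)
        grid_q = np.geomspace(10, 1000, 61)
        best, popt = np.inf, p0
        for wc in grid_wc:
            for q in grid_q:
                shape = lorentzian_mode(freqs, wc, q, 1.0)
                scale = float(np.dot(shape, nu1s) / np.dot(shape, shape))
                err = float(np.sum((nu1s - scale * shape) ** 2))
                if err < best and scale > 0:
                    best, popt = err, [wc, q, scale]
    resid = nu1s - lorentzian_mode(freqs, *popt)
    prof = ResonatorProfile(
        omega_c=float(popt[0]), q_factor=float(popt[1]),
        nu1_max=float(popt[2]),
        points=[(fq, f.nu1, f.accepted) for fq, f in points],
        fit_residual=float(np.sqrt(np.mean(resid ** 2))))
    return prof


def needs_recentre(profile: ResonatorProfile, initial_guess_ghz: float,
                   threshold_mhz: float = RECENTRE_THRESHOLD_MHZ) -> bool:
    """True when the fitted centre moved > 100 MHz from the initial guess,
    in which case the profile (and field sweep) must be re-measured."""
    return abs(profile.omega_c - initial_guess_ghz) * 1e3 > threshold_mhz
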