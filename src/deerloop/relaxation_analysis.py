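"""Echo-decay analysis for delay planning.

Carr-Purcell-2 decays (five-pulse planning) and refocused-echo decays
(four-pulse planning) are fitted with a stretched exponential
A exp(-(t/Tm)^xi); the normalised evaluator V~(tau_evo) in [0, 1] feeds the
SNR-vs-evolution-time planner. For 2D refocused-echo maps the per-tau2
optimal tau1 ridge is extracted and compared against the common fixed
tau1 = 400 ns slice. A pump pulse present during the decay reduces the echo
amplitude by a global multiplicative factor without changing the shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DecayCurve:
    """Time-amplitude decay trace; times in us, centre-to-centre."""

    times: np.ndarray
    amplitude: np.ndarray
    kind: str = "cp2"   # cp2 | refocused_1d | refocused_2d_slice | srt_scan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")


@dataclass
class DecayFit:
    """Stretched-exponential decay fit with a normalised evaluator."""

    Tm: float            # us
    xi_m: float
    A: float
    residual_rms: float = 0.0
    empirical: Callable | None = None   # optional spline evaluator

    def v_norm(self, tau_evo_us) -> np.ndarray:
        """Normalised decay V~(tau_evo), V~(0) = 1, clipped to [0, 1]."""
        tau = np.asarray(tau_evo_us, dtype=float)
        if self.empirical is not None:
            return np.clip(self.empirical(tau), 0.0, 1.0)
        return np.clip(np.exp(-((np.clip(tau, 0.0, None) / self.Tm)
                                ** self.xi_m)), 0.0, 1.0)

    def __call__(self, tau_evo_us) -> np.ndarray:
        return self.A * self.v_norm(tau_evo_us)

    def to_json(self) -> str:
        return json.dumps({"Tm_us": self.Tm, "xi_m": self.xi_m, "A": self.A,
                           "residual_rms": self.residual_rms})


def fit_decay(curve: DecayCurve, empirical: bool = False) -> DecayFit:
    """Fit A exp(-(t/Tm)^xi) to a decay trace.

    ``empirical=True`` additionally attaches a monotone interpolated
    evaluator for fixtures whose decay is not stretched-exponential.
    Rising traces are rejected.
    """
    t, y = curve.times, curve.amplitude
    if t.size < 10:
        raise ValueError("need at least 10 points")
    # reject clearly rising data (recovery curves belong elsewhere)
    head = y[: max(3, t.size // 5)].mean()
    tail = y[-max(3, t.size // 5):].mean()
    if tail > head:
        raise ValueError("decay trace rises; not a transverse decay")

    def f(tt, tm, xi, a):
        return a * np.exp(-((tt / tm) ** xi))

    if y[0] > 0:
        t1_0 = t[min(int(np.searchsorted(-y, -y[0] / np.e)), t.size - 1)]
    else:
        t1_0 = t[t.size // 2]
    t1_0 = float(np.clip(t1_0, t[t > 0].min() if np.any(t > 0) else 1e-3,
                         t[-1]))
    popt, _ = curve_fit(f, t, y, p0=[t1_0, 1.0, float(y[0])],
                        bounds=([1e-6, 0.2, 1e-12],
                                [np.inf, 6.0, np.inf]), maxfev=20000)
    resid = y - f(t, *popt)
    fit = DecayFit(Tm=float(popt[0]), xi_m=float(popt[1]), A=float(popt[2]),
                   residual_rms=float(np.sqrt(np.mean(resid ** 2))))
    if empirical:
        ynorm = np.clip(y / max(y[0], 1e-12), 0.0, 1.0)
        ymono = np.minimum.accumulate(ynorm)
        fit.empirical = lambda tau: np.interp(tau, t, ymono, left=1.0,
                                              right=float(ymono[-1]))
    return fit


def ridge_from_2d(tau1_us: np.ndarray, tau2_us: np.ndarray,
                  grid: np.ndarray, smooth_window: int = 3,
                  fixed_tau1_us: float = 0.4) -> pd.DataFrame:
    """Optimal tau1 per tau2 from a 2D refocused-echo map.

    ``grid`` has shape (n_tau1, n_tau2). A light moving average along tau1
    precedes the argmax. The returned frame also carries the amplitude of
    the fixed tau1 = 400 ns slice for comparison.
    """
    tau1 = np.asarray(tau1_us, dtype=float)
    tau2 = np.asarray(tau2_us, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (tau1.size, tau2.size):
        raise ValueError("ragged grid: shape does not match axes")
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        sm = np.apply_along_axis(
            lambda col: np.convolve(col, kern, mode="same"), 0, grid)
    else:
        sm = grid
    idx = np.argmax(sm, axis=0)
    i_fixed = int(np.argmin(np.abs(tau1 - fixed_tau1_us)))
    return pd.DataFrame({
        "tau2_us": tau2,
        "best_tau1_us": tau1[idx],
        "amplitude": grid[idx, np.arange(tau2.size)],
        "amplitude_fixed_tau1": grid[i_fixed, :],
    })


def apply_pump_reduction(fit: DecayFit, factor: float) -> DecayFit:
    """Scale the decay amplitude by the pump-induced echo-reduction factor
    (shape unchanged)."""
    if not 0 < factor <= 1:
        raise ValueError("reduction factor must lie in (0, 1]")
    return DecayFit(Tm=fit.Tm, xi_m=fit.xi_m, A=fit.A * factor,
                    residual_rms=fit.residual_rms, empirical=fit.empirical)
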