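"""Echo-detected field sweep (EDFS) processing.

The EDFS records the Hahn-echo amplitude as a function of magnetic field and
is the first setup experiment: it yields the EPR absorption line shape and an
improved effective gyromagnetic ratio ``gamma_eff = carrier / B_max`` that
absorbs any static field offset. All later field <-> frequency conversions go
through ``gamma_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


class NoSpectrumError(ValueError):
    """Raised when the field sweep contains no detectable resonance line."""


@dataclass
class Spectrum:
    """EPR absorption line on a frequency-offset axis.

    Attributes
    ----------
    offsets:
        Frequency offsets from the observer carrier, MHz, strictly increasing.
    amplitude:
        Non-negative absorption amplitude, normalised so max(amplitude) = 1.
    gamma_eff:
        Effective gyromagnetic ratio, MHz/mT.
    carrier:
        Observer microwave frequency, GHz.
    field_at_max:
        Field position of the spectral maximum, mT.
    """

    offsets: np.ndarray
    amplitude: np.ndarray
    gamma_eff: float
    carrier: float
    field_at_max: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.offsets.shape != self.amplitude.shape:
            raise ValueError("offsets and amplitude must have the same shape")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")

    def __call__(self, offsets_mhz: np.ndarray) -> np.ndarray:
        """Linear interpolation of the amplitude; zero outside the support."""
        return np.interp(offsets_mhz, self.offsets, self.amplitude,
                         left=0.0, right=0.0)

    @property
    def max_offset(self) -> float:
        """Offset (MHz) of the spectral maximum."""
        return float(self.offsets[int(np.argmax(self.amplitude))])

    def bandwidth(self, threshold: float = 0.05) -> float:
        """Spectral width (MHz): the contiguous interval around the maximum
        where amplitude >= threshold * max (contiguity makes the estimate
        robust to residual noise bumps in the baseline)."""
        above = self.amplitude >= threshold * self.amplitude.max()
        i = int(np.argmax(self.amplitude))
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        return float(self.offsets[hi] - self.offsets[lo])

    def shifted(self, delta_mhz: float) -> "Spectrum":
        """Spectrum translated by ``delta_mhz`` along the offset axis."""
        return Spectrum(self.offsets + delta_mhz, self.amplitude.copy(),
                        self.gamma_eff, self.carrier, self.field_at_max)


def process_edfs(
    field_mt: np.ndarray,
    signal: np.ndarray,
    carrier_ghz: float,
    lam: float | None = None,
    noise_floor_snr: float = 3.0,
) -> Spectrum:
    """Smooth an echo-detected field sweep and build a :class:`Spectrum`.

    A smoothing spline (stiffness by generalised cross-validation unless
    ``lam`` overrides it) suppresses noise; the field at the smoothed maximum
    defines ``gamma_eff = carrier / B_max``.

    Parameters
    ----------
    field_mt:
        Magnetic-field axis, mT, >= 20 points spanning the line.
    signal:
        Echo amplitude, arbitrary units.
    carrier_ghz:
        Observer microwave frequency, GHz.
    lam:
        Optional smoothing-spline stiffness override.
    noise_floor_snr:
        Peak-to-noise ratio below which the sweep is declared empty.
    """
    field_mt = np.asarray(field_mt, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if field_mt.size < 20:
        raise ValueError("need at least 20 field points spanning the line")
    order = np.argsort(field_mt)
    field_mt, signal = field_mt[order], signal[order]

    # noise estimate from first differences (signal is smooth on this scale)
    noise = np.std(np.diff(signal)) / np.sqrt(2.0)
    peak = signal.max() - np.median(signal)
    if noise > 0 and peak <= noise_floor_snr * noise:
        raise NoSpectrumError("no spectrum detected: peak below noise floor")

    spline = make_smoothing_spline(field_mt, signal, lam=lam)
    dense = np.linspace(field_mt[0], field_mt[-1], 10 * field_mt.size)
    smooth = spline(dense)
    field_at_max = _refine_max(dense, smooth)

    gamma_eff = carrier_ghz * 1e3 / field_at_max  # MHz/mT
    offsets = gamma_eff * field_mt - carrier_ghz * 1e3
    amplitude = np.clip(spline(field_mt), 0.0, None)
    amplitude /= amplitude.max()
    return Spectrum(offsets, amplitude, gamma_eff, carrier_ghz, field_at_max)


def _refine_max(x: np.ndarray, y: np.ndarray) -> float:
    """Continuous peak position: parabola vertex fitted to the contiguous
    top region (>= 80% of max) of the smoothed curve. Averaging over the
    top suppresses residual noise jitter that a raw argmax would keep."""
    i = int(np.argmax(y))
    thresh = 0.8 * y[i]
    lo = i
    while lo > 0 and y[lo - 1] >= thresh:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] >= thresh:
        hi += 1
    if hi - lo < 4:
        return float(x[i])
    xs, ys = x[lo:hi + 1], y[lo:hi + 1]
    c = np.polyfit(xs - xs.mean(), ys, 2)
    if c[0] >= 0:            # degenerate curvature: keep the grid argmax
        return float(x[i])
    vertex = xs.mean() - c[1] / (2.0 * c[0])
    if not x[lo] <= vertex <= x[hi]:
        return float(x[i])
    return float(vertex)


def field_for_frequency(spectrum: Spectrum, target_ghz: float) -> float:
    """Field (mT) at which ``target_ghz`` is on resonance, via gamma_eff."""
    if not np.isfinite(spectrum.gamma_eff) or spectrum.gamma_eff <= 0:
        raise ValueError("gamma_eff is not set")
    return target_ghz * 1e3 / spectrum.gamma_eff


def frequency_for_field(spectrum: Spectrum, field_mt: float) -> float:
    """Inverse of :func:`field_for_frequency`: resonance frequency in GHz."""
    return spectrum.gamma_eff * field_mt / 1e3


def read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column text file (field mT, amplitude)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     names=["field_mT", "amplitude"], header=None)
    return df["field_mT"].to_numpy(float), df["amplitude"].to_numpy(float)


def write_two_column(path, field_mt: np.ndarray, amplitude: np.ndarray) -> None:
    pd.DataFrame({"field_mT": field_mt, "amplitude": amplitude}).to_csv(
        path, index=False, header=False)
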