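"""Pulse waveforms and two-level excitation/inversion profiles.

Waveforms (rectangular, Gaussian, linear-chirp rectangular, hyperbolic
secant) are sampled as complex nu1 envelopes, filtered by the resonator
transfer function H(omega) in the frequency domain (amplitude filter only),
and propagated offset-by-offset as piecewise-constant two-level rotations.
The resulting profiles are the per-pulse factors of the exclusive pump /
observe probabilities used in pulse-placement optimisation.

Two bandwidth conventions coexist for rectangular pulses and are named
explicitly: the *design* bandwidth 1/(2 t_p) used by the observer-length
rule (pinned by the printed 8 / 12.5 ns choices at nu1max = 70 / 45 MHz) and
the *report* bandwidth 1/t_p used in tabular summaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .resonator_profile import ResonatorProfile

#: fraction of nu1max the observer excitation bandwidth is set to
OBSERVER_BANDWIDTH_FRACTION = 0.9
#: cap of the excitation bandwidth as a fraction of the available bandwidth
AVAILABLE_BANDWIDTH_CAP = 0.4


class InsufficientB1Error(RuntimeError):
    """Pulse amplitude demand exceeds the available nutation frequency."""

    def __init__(self, demand_mhz: float, available_mhz: float):
        self.demand_mhz = demand_mhz
        self.available_mhz = available_mhz
        self.shortfall_mhz = demand_mhz - available_mhz
        super().__init__(
            f"insufficient B1: demand {demand_mhz:.1f} MHz exceeds "
            f"available {available_mhz:.1f} MHz "
            f"(shortfall {self.shortfall_mhz:.1f} MHz)")


@dataclass
class PulseSpec:
    """Description of one microwave pulse.

    length is the full pulse length in ns (centre-referenced timing);
    centre_offset is the carrier offset in MHz; sweep_bandwidth is the
    frequency-sweep width in MHz (0 for monochromatic pulses);
    amplitude_scale is the fraction of the available nu1 a swept pulse uses.
    """

    shape: str                       # rect | gaussian | chirp_rect | hyperbolic_secant
    length: float                    # ns
    flip: str = "pi"                 # pi | pi_half
    centre_offset: float = 0.0       # MHz
    sweep_bandwidth: float = 0.0     # MHz
    amplitude_scale: float = 1.0
    amplitude_mhz: float | None = None  # explicit nu1 demand override
    edge_smoothing: float = 0.1         # quarter-sine rise/fall fraction (swept)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.sweep_bandwidth < 0:
            raise ValueError("sweep_bandwidth must be non-negative")
        if self.shape in ("chirp_rect", "hyperbolic_secant") \
                and self.sweep_bandwidth <= 0:
            raise ValueError("swept pulses need sweep_bandwidth > 0")
        if self.shape not in ("rect", "gaussian", "chirp_rect",
                              "hyperbolic_secant"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")

    @property
    def is_swept(self) -> bool:
        return self.sweep_bandwidth > 0

    def bandwidth(self, convention: str = "report") -> float:
        """Excitation bandwidth in MHz under the named convention."""
        if self.is_swept:
            return self.sweep_bandwidth
        factor = {"report": 1.0, "design": 0.5}[convention]
        return factor * 1e3 / self.length

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class ExcitationProfile:
    """Simulated flip behaviour of one pulse vs frequency offset."""

    offsets: np.ndarray   # MHz
    p_excite: np.ndarray  # transverse conversion |Mxy|, in [0, 1]
    p_invert: np.ndarray  # inversion probability (1 - Mz)/2, in [0, 1]


def _flip_angle(flip: str) -> float:
    return {"pi": np.pi, "pi_half": np.pi / 2}[flip]


def sample_waveform(pulse: PulseSpec, dt_ns: float = 1.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the complex nu1 envelope (MHz) of a pulse on a <= 1 ns grid.

    The envelope is expressed in the rotating frame of the pulse centre
    frequency; chirp/sech sweeps appear as quadratic/log-cosh phase ramps.
    """
    dt = min(dt_ns, pulse.length / 64.0)
    n = max(int(round(pulse.length / dt)), 8)
    dt = pulse.length / n
    t = (np.arange(n) + 0.5) * dt                  # ns
    tc = pulse.length / 2.0
    theta = _flip_angle(pulse.flip)

    if pulse.shape == "rect":
        # theta = 2 pi * 1e-3 * nu1 * t_p  ->  nu1 [MHz]
        nu1 = theta / (2e-3 * np.pi * pulse.length)
        env = np.full(n, nu1, dtype=complex)
    elif pulse.shape == "gaussian":
        fwhm = pulse.length / 2.0
        sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        shape = np.exp(-0.5 * ((t - tc) / sig) ** 2)
        # calibrate the peak so the integrated rotation equals theta
        peak = theta / (2e-3 * np.pi * np.sum(shape) * dt)
        env = (peak * shape).astype(complex)
    elif pulse.shape == "chirp_rect":
        amp = pulse.amplitude_mhz
        if amp is None:
            raise ValueError("chirp_rect needs amplitude_mhz "
                             "(set via resonator in simulate_profile)")
        rate = pulse.sweep_bandwidth / pulse.length          # MHz / ns
        phase = np.pi * 1e-3 * rate * (t - tc) ** 2          # rad
        env = amp * _edge_ramp(t, pulse) * np.exp(1j * phase)
    else:  # hyperbolic_secant
        amp = pulse.amplitude_mhz
        if amp is None:
            raise ValueError("hyperbolic_secant needs amplitude_mhz")
        beta = 5.3
        x = beta * (2.0 * (t - tc) / pulse.length)
        # instantaneous frequency (BW/2) tanh(x); integrate for phase
        phase = (2e-3 * np.pi) * (pulse.sweep_bandwidth / 2.0) \
            * (pulse.length / (2.0 * beta)) * np.log(np.cosh(x))
        env = amp / np.cosh(x) * np.exp(1j * phase)
    return t, env


def _edge_ramp(t: np.ndarray, pulse: PulseSpec) -> np.ndarray:
    """Quarter-sine rise/fall applied to swept rectangular envelopes;
    suppresses the Fresnel ripple of abrupt edges (standard AWG practice)."""
    if pulse.edge_smoothing <= 0:
        return np.ones_like(t)
    tr = pulse.edge_smoothing * pulse.length
    ramp = np.ones_like(t)
    rise = t < tr
    fall = t > pulse.length - tr
    ramp[rise] = np.sin(0.5 * np.pi * t[rise] / tr)
    ramp[fall] = np.sin(0.5 * np.pi * (pulse.length - t[fall]) / tr)
    return ramp


def _apply_transfer(env: np.ndarray, dt: float, centre_offset: float,
                    resonator: ResonatorProfile | None,
                    carrier_ghz: float | None) -> np.ndarray:
    """Filter the envelope by H(omega) in the frequency domain.

    The envelope is zero-padded (4x each side) so the pulse edges are part
    of the transformed signal; without padding a rectangular envelope is
    pure DC and the filter would never act."""
    if resonator is None or carrier_ghz is None:
        return env
    n = env.size
    padded = np.concatenate([np.zeros(4 * n, complex), env,
                             np.zeros(4 * n, complex)])
    spec = np.fft.fft(padded)
    f = np.fft.fftfreq(padded.size, d=dt) * 1e3  # MHz relative to centre
    abs_ghz = carrier_ghz + (centre_offset + f) * 1e-3
    h = resonator.transfer(np.clip(abs_ghz, 1e-3, None))
    out = np.fft.ifft(spec * h)
    return out[4 * n: 5 * n]


def simulate_profile(pulse: PulseSpec, resonator: ResonatorProfile | None,
                     offsets_mhz: np.ndarray,
                     carrier_ghz: float | None = None,
                     dt_ns: float = 1.0) -> ExcitationProfile:
    """Two-level excitation/inversion profile of a pulse.

    The waveform is sampled, amplitude-filtered by the resonator transfer
    function, then propagated offset-by-offset as piecewise-constant
    rotations of a magnetisation starting at +z. Swept pulses with no
    explicit amplitude use the full available nu1 (amplitude_scale x
    nu1max). A demand above the available nu1 raises
    :class:`InsufficientB1Error` reporting the shortfall.
    """
    offsets = np.asarray(offsets_mhz, dtype=float)
    pulse = _with_amplitude(pulse, resonator)
    t, env = sample_waveform(pulse, dt_ns)
    dt = t[1] - t[0] if t.size > 1 else pulse.length

    if resonator is not None:
        demand = float(np.max(np.abs(env)))
        available = pulse.amplitude_scale * resonator.nu1_max
        if demand > available * (1.0 + 1e-9):
            raise InsufficientB1Error(demand, available)

    env = _apply_transfer(env, dt, pulse.centre_offset, resonator,
                          carrier_ghz)

    # piecewise-constant two-level propagation, vectorised over offsets
    mx = np.zeros_like(offsets)
    my = np.zeros_like(offsets)
    mz = np.ones_like(offsets)
    delta = offsets - pulse.centre_offset        # MHz, envelope frame
    two_pi = 2e-3 * np.pi                        # rad per (MHz * ns)
    for e in env:
        bx, by, bz = e.real, e.imag, delta
        beff = np.sqrt(bx * bx + by * by + bz * bz)
        ang = two_pi * beff * dt
        safe = np.where(beff > 0, beff, 1.0)
        nx, ny, nz = bx / safe, by / safe, bz / safe
        c, s = np.cos(ang), np.sin(ang)
        dot = nx * mx + ny * my + nz * mz
        cx = ny * mz - nz * my
        cy = nz * mx - nx * mz
        cz = nx * my - ny * mx
        mx = mx * c + cx * s + nx * dot * (1 - c)
        my = my * c + cy * s + ny * dot * (1 - c)
        mz = mz * c + cz * s + nz * dot * (1 - c)

    p_invert = np.clip((1.0 - mz) / 2.0, 0.0, 1.0)
    p_excite = np.clip(np.sqrt(mx * mx + my * my), 0.0, 1.0)
    return ExcitationProfile(offsets=offsets, p_excite=p_excite,
                             p_invert=p_invert)


def _with_amplitude(pulse: PulseSpec,
                    resonator: ResonatorProfile | None) -> PulseSpec:
    """Resolve the nu1 amplitude of swept pulses from the resonator."""
    if not pulse.is_swept or pulse.amplitude_mhz is not None:
        return pulse
    if resonator is None:
        raise ValueError("swept pulse needs a resonator or amplitude_mhz")
    return PulseSpec(pulse.shape, pulse.length, pulse.flip,
                     pulse.centre_offset, pulse.sweep_bandwidth,
                     pulse.amplitude_scale,
                     amplitude_mhz=pulse.amplitude_scale * resonator.nu1_max,
                     edge_smoothing=pulse.edge_smoothing)


def observer_pulse_lengths(nu1_max: float,
                           available_bandwidth: float | None = None,
                           granularity_ns: float | None = 2.0
                           ) -> tuple[float, float]:
    """Observer pi/2 and pi lengths (ns) from the bandwidth rules.

    The pi/2 length is set so its design bandwidth 1/(2 t) equals 90% of
    nu1max: t = 1/(2 * 0.9 * nu1max). If that bandwidth exceeds 40% of the
    available bandwidth (resonator or spectrum, whichever is narrower) the
    length is recomputed from the 40% cap. The pi pulses share shape and
    length at doubled amplitude. ``granularity_ns=None`` skips hardware
    rounding.
    """
    if nu1_max <= 0:
        raise ValueError("nu1_max must be positive")
    bw = OBSERVER_BANDWIDTH_FRACTION * nu1_max
    if available_bandwidth is not None:
        bw = min(bw, AVAILABLE_BANDWIDTH_CAP * available_bandwidth)
    length = 1e3 / (2.0 * bw)
    if granularity_ns:
        length = max(granularity_ns,
                     granularity_ns * round(length / granularity_ns))
    return length, length


def observer_pulses(nu1_max: float, available_bandwidth: float | None = None,
                    centre_offset: float = 0.0,
                    granularity_ns: float | None = 2.0
                    ) -> tuple[PulseSpec, PulseSpec, PulseSpec]:
    """(pi/2, pi, pi) rectangular observer pulse train."""
    t_half, t_pi = observer_pulse_lengths(nu1_max, available_bandwidth,
                                          granularity_ns)
    half = PulseSpec("rect", t_half, "pi_half", centre_offset)
    pi1 = PulseSpec("rect", t_pi, "pi", centre_offset)
    pi2 = PulseSpec("rect", t_pi, "pi", centre_offset)
    return half, pi1, pi2


def write_profile(path, profile: ExcitationProfile) -> None:
    """Dump a profile as three-column text (offset, p_excite, p_invert)."""
    np.savetxt(path, np.column_stack(
        [profile.offsets, profile.p_excite, profile.p_invert]),
        header="offset_MHz p_excite p_invert")
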