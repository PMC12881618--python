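"""Resonant fiber-cantilever scanner: beam mechanics, spiral drive, tip trajectories.

A single-mode fiber cantilever glued to the tip of a two-axis piezo tube is
driven near its first flexural resonance. Two sinusoids with a 90° relative
phase on the ±X/±Y electrodes, with a slowly growing amplitude, sweep the fiber
tip along an outward spiral; reversing the drive phase (180°) actively brakes
the oscillation, after which the fiber rings down freely. One full
imaging/braking/decay cycle produces one volumetric frame.

The first flexural resonance of a circular-section cantilever is

    omega = beta * sqrt(E / rho) * R / L**2

with ``beta = (k1*L)**2 / 2 ≈ 1.7578`` for the first mode, because the
Euler–Bernoulli radius of gyration of a solid circular section is R/2
(``sqrt(E I / rho A) = (R/2) sqrt(E/rho)``) and ``k1*L = 1.87510407`` is the
first root of ``cos(kL) cosh(kL) = -1``.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FIRST_MODE_CONSTANT",
    "CantileverSpec",
    "ScanProtocol",
    "ScanPhase",
    "Trajectory",
    "resonant_frequency",
    "drive_waveform",
    "simulate_trajectory",
]

#: beta for the first flexural mode of a solid circular-section cantilever,
#: (k1 L)^2 / 2 with k1 L the first root of cos(kL)cosh(kL) = -1.
FIRST_MODE_CONSTANT = 1.8751040687119611**2 / 2.0

#: Default trajectory sampling rate (Hz).  Matches the maximum laser PRF so
#: trigger-position lookup is pure interpolation, never extrapolation.
DEFAULT_SAMPLE_RATE = 500e3


class ScanPhase(enum.IntEnum):
    """Phase labels for each trajectory sample."""

    IMAGING = 0
    BRAKING = 1
    DECAY = 2


@dataclass(frozen=True)
class CantileverSpec:
    """Physical description of the fiber cantilever.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E of the fiber material, Pa (fused silica ≈ 73 GPa).
    density : float
        Mass density rho, kg/m^3 (fused silica ≈ 2200).
    radius : float
        Fiber radius R (cladding), m.
    length : float
        Free cantilever length L, m.
    mode_constant : float
        Dimensionless mode constant beta; defaults to the first flexural mode.
    """

    youngs_modulus: float = 73e9
    density: float = 2200.0
    radius: float = 62.5e-6
    length: float = 18e-3
    mode_constant: float = FIRST_MODE_CONSTANT

    def __post_init__(self) -> None:
        for name in ("youngs_modulus", "density", "radius", "length", "mode_constant"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CantileverSpec.{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "youngs_modulus": self.youngs_modulus,
            "density": self.density,
            "radius": self.radius,
            "length": self.length,
            "mode_constant": self.mode_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CantileverSpec":
        return cls(**d)


def resonant_frequency(spec: CantileverSpec) -> float:
    """Flexural resonance of the cantilever in Hz.

    ``omega = beta * sqrt(E/rho) * R / L**2``; returns ``omega / (2 pi)``.
    """
    omega = (
        spec.mode_constant
        * math.sqrt(spec.youngs_modulus / spec.density)
        * spec.radius
        / spec.length**2
    )
    return omega / (2.0 * math.pi)


@dataclass(frozen=True)
class ScanProtocol:
    """Spiral scan drive plan: one imaging/braking/decay cycle.

    Durations in seconds; ``max_radius`` is the tip radius reached at the end
    of the imaging ramp (FOV radius).  ``decay_time_constant`` defaults to
    ``decay_duration / 3`` so the free-decay envelope falls below 5% of its
    starting value by the end of the cycle.  ``brake_end_fraction`` is the
    oscillation amplitude (as a fraction of ``max_radius``) remaining when
    active braking ends; the drive amplitude ramps linearly down to it.
    """

    scan_frequency: float = 333.0
    imaging_duration: float = 1.0
    braking_duration: float = 0.2
    decay_duration: float = 0.3
    max_radius: float = 1.3e-3
    ramp_shape: str = "linear"
    decay_time_constant: float | None = None
    brake_end_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.scan_frequency <= 0:
            raise ValueError("scan_frequency must be > 0")
        if self.max_radius <= 0:
            raise ValueError("max_radius must be > 0")
        for name in ("imaging_duration", "braking_duration", "decay_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ramp_shape != "linear":
            raise ValueError(f"unsupported ramp_shape: {self.ramp_shape!r}")
        if not 0.0 <= self.brake_end_fraction <= 1.0:
            raise ValueError("brake_end_fraction must lie in [0, 1]")

    @property
    def cycle_duration(self) -> float:
        """Total duration of one volume: imaging + braking + decay."""
        return self.imaging_duration + self.braking_duration + self.decay_duration

    @property
    def tau_decay(self) -> float:
        if self.decay_time_constant is not None:
            return self.decay_time_constant
        return self.decay_duration / 3.0 if self.decay_duration > 0 else 1e-3

    def to_dict(self) -> dict:
        return {
            "scan_frequency": self.scan_frequency,
            "imaging_duration": self.imaging_duration,
            "braking_duration": self.braking_duration,
            "decay_duration": self.decay_duration,
            "max_radius": self.max_radius,
            "ramp_shape": self.ramp_shape,
            "decay_time_constant": self.decay_time_constant,
            "brake_end_fraction": self.brake_end_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        return cls(**d)


def _amplitude_and_sign(protocol: ScanProtocol, times: np.ndarray):
    """Drive amplitude envelope in [0, 1] and drive sign per sample.

    Sign is +1 while imaging, -1 during active braking (180° phase-opposed
    drive), 0 during free decay.
    """
    t = np.asarray(times, dtype=float)
    t_img = protocol.imaging_duration
    t_brk = t_img + protocol.braking_duration
    amp = np.zeros_like(t)
    sign = np.zeros_like(t)

    imaging = (t >= 0) & (t < t_img)
    amp[imaging] = t[imaging] / t_img if t_img > 0 else 0.0
    sign[imaging] = 1.0

    braking = (t >= t_img) & (t < t_brk)
    if protocol.braking_duration > 0:
        frac = (t[braking] - t_img) / protocol.braking_duration
        amp[braking] = 1.0 + (protocol.brake_end_fraction - 1.0) * frac
        sign[braking] = -1.0
    return amp, sign


def drive_waveform(protocol: ScanProtocol, times: np.ndarray) -> np.ndarray:
    """Two-channel normalized drive voltages at the given times.

    Returns an array of shape (N, 2): column 0 is the X electrode pair,
    column 1 the Y pair.  Y leads X by a quarter period (x = a sin, y = a cos;
    counter-clockwise spiral).  During braking the same sinusoids are emitted
    with a 180° phase flip and a linearly falling amplitude; during free decay
    both channels are zero.

    Raises ``ValueError`` for times outside one full cycle.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(t > protocol.cycle_duration + 1e-12):
        raise ValueError("times must lie within one full scan cycle")
    amp, sign = _amplitude_and_sign(protocol, t)
    phase = 2.0 * np.pi * protocol.scan_frequency * t
    out = np.empty(t.shape + (2,), dtype=float)
    out[..., 0] = sign * amp * np.sin(phase)
    out[..., 1] = sign * amp * np.cos(phase)
    return out


@dataclass
class Trajectory:
    """Time-stamped tip path in the probe frame (origin at scan center).

    ``positions`` has shape (N, 2) in meters; ``phase_labels`` holds a
    :class:`ScanPhase` value per sample.
    """

    times: np.ndarray
    positions: np.ndarray
    phase_labels: np.ndarray
    max_radius: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.max_radius > 0:
            r = np.hypot(self.positions[:, 0], self.positions[:, 1])
            if np.any(r > self.max_radius * 1.02):
                raise ValueError("trajectory exceeds max_radius beyond tolerance")

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    def interpolate(self, query_times: np.ndarray) -> np.ndarray:
        """Linearly interpolated (x, y) at the given times (shape (M, 2)).

        Raises ``ValueError`` if any query time falls outside the recorded span.
        """
        q = np.asarray(query_times, dtype=float)
        if q.size and (q.min() < self.times[0] - 1e-12 or q.max() > self.times[-1] + 1e-12):
            raise ValueError("query times outside trajectory span")
        x = np.interp(q, self.times, self.positions[:, 0])
        y = np.interp(q, self.times, self.positions[:, 1])
        return np.column_stack([x, y])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "x", "y", "phase"])
            for t, (x, y), p in zip(self.times, self.positions, self.phase_labels):
                w.writerow([repr(float(t)), repr(float(x)), repr(float(y)),
                            ScanPhase(int(p)).name.lower()])

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        times, xs, ys, phases = [], [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                times.append(float(row["t"]))
                xs.append(float(row["x"]))
                ys.append(float(row["y"]))
                phases.append(ScanPhase[row["phase"].upper()])
        return cls(
            np.array(times), np.column_stack([xs, ys]), np.array(phases, dtype=int)
        )


def _phase_labels(protocol: ScanProtocol, t: np.ndarray) -> np.ndarray:
    labels = np.full(t.shape, int(ScanPhase.DECAY))
    labels[t < protocol.imaging_duration + protocol.braking_duration] = int(
        ScanPhase.BRAKING
    )
    labels[t < protocol.imaging_duration] = int(ScanPhase.IMAGING)
    return labels


def _kinematic_positions(protocol: ScanProtocol, t: np.ndarray) -> np.ndarray:
    t_img = protocol.imaging_duration
    t_brk = t_img + protocol.braking_duration
    amp = np.zeros_like(t)

    imaging = t < t_img
    amp[imaging] = (t[imaging] / t_img) if t_img > 0 else 0.0

    braking = (t >= t_img) & (t < t_brk)
    if protocol.braking_duration > 0:
        frac = (t[braking] - t_img) / protocol.braking_duration
        amp[braking] = 1.0 + (protocol.brake_end_fraction - 1.0) * frac

    decay = t >= t_brk
    amp[decay] = protocol.brake_end_fraction * np.exp(
        -(t[decay] - t_brk) / protocol.tau_decay
    )

    r = protocol.max_radius * amp
    phase = 2.0 * np.pi * protocol.scan_frequency * t
    return np.column_stack([r * np.sin(phase), r * np.cos(phase)])


def _integrate_axis(
    drive: callable,
    t_eval: np.ndarray,
    f0: float,
    quality_factor: float,
) -> np.ndarray:
    """Displacement of ``u'' + (w0/Q) u' + w0^2 u = w0^2 * drive(t)``.

    ``drive`` maps a time array to a normalized forcing amplitude; the w0^2
    scaling makes the static response equal the drive, so at resonance the
    steady-state amplitude is Q times the drive amplitude.
    """
    w0 = 2.0 * np.pi * f0

    def rhs(t, y):
        u, v = y
        return [v, w0 * w0 * (float(drive(np.array([t]))[0]) - u) - (w0 / quality_factor) * v]

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        [0.0, 0.0],
        t_eval=t_eval,
        max_step=1.0 / (20.0 * f0),
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"oscillator integration failed: {sol.message}")
    return sol.y[0]


def _dynamic_positions(
    protocol: ScanProtocol, spec: CantileverSpec, t: np.ndarray
) -> np.ndarray:
    f0 = resonant_frequency(spec)
    q = np.pi * protocol.scan_frequency * protocol.tau_decay

    def drive_x(tt):
        amp, sign = _amplitude_and_sign(protocol, tt)
        return sign * amp * np.sin(2.0 * np.pi * protocol.scan_frequency * tt)

    def drive_y(tt):
        amp, sign = _amplitude_and_sign(protocol, tt)
        return sign * amp * np.cos(2.0 * np.pi * protocol.scan_frequency * tt)

    x = _integrate_axis(drive_x, t, f0, q)
    y = _integrate_axis(drive_y, t, f0, q)
    pos = np.column_stack([x, y])

    # scale so the steady-state imaging radius reaches max_radius
    period = 1.0 / protocol.scan_frequency
    tail = (t >= protocol.imaging_duration - period) & (t < protocol.imaging_duration)
    r_end = np.hypot(x[tail], y[tail]).mean() if tail.any() else np.hypot(x, y).max()
    if r_end <= 0:
        raise RuntimeError("dynamic model produced zero response")
    return pos * (protocol.max_radius / r_end)


def simulate_trajectory(
    protocol: ScanProtocol,
    spec: CantileverSpec | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    model: str = "kinematic",
) -> Trajectory:
    """Tip trajectory over one full scan cycle.

    ``model="kinematic"`` evaluates the ideal spiral in closed form: radius
    follows the linear drive ramp during imaging, shrinks linearly during
    braking, and rings down exponentially (time constant ``tau_decay``) in
    free decay, always rotating at ``scan_frequency``.

    ``model="dynamic"`` integrates a driven damped harmonic oscillator per
    axis — natural frequency from :func:`resonant_frequency`, quality factor
    ``Q = pi * f * tau_decay`` — and rescales the displacement so the
    steady-state imaging radius matches ``max_radius``.

    Raises a sampling error when ``sample_rate < 10 * scan_frequency``.
    """
    if sample_rate < 10.0 * protocol.scan_frequency:
        raise ValueError(
            "sample_rate must be at least 10x the scan frequency "
            f"({sample_rate:g} < {10 * protocol.scan_frequency:g})"
        )
    n = int(round(protocol.cycle_duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    t = t[t <= protocol.cycle_duration + 1e-12]

    if model == "kinematic":
        pos = _kinematic_positions(protocol, t)
    elif model == "dynamic":
        if spec is None:
            spec = CantileverSpec()
        pos = _dynamic_positions(protocol, spec, t)
    else:
        raise ValueError(f"unknown trajectory model: {model!r}")

    return Trajectory(t, pos, _phase_labels(protocol, t), max_radius=protocol.max_radius)
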