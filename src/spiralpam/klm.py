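"""KLM transmission-line model of a layered piezoelectric transducer.

The Krimholtz–Leedom–Matthaei (KLM) equivalent circuit represents the piezo
plate as an acoustic transmission line tapped at its midpoint through a
frequency-dependent ideal transformer, with the electrical port behind the
clamped capacitance C0 and a series reactance X1.  Matching and backing
layers are ordinary acoustic transmission-line two-ports; the front and back
media terminate the line.

Circuit constants used here (theta = omega * d / v, Zc = rho*v*A):

    C0   = eps_S * eps0 * A / d
    X1   = kt^2 * sin(theta) / (theta * omega * C0)
    phi  = kt * sqrt(pi / (omega0 * C0 * Zc)) * sin(theta/2) / (theta/2)

with omega0 = pi*v/d.  These reproduce the Mason-model electrical input
impedance

    Zin = 1/(j w C0) * [1 - kt^2/theta *
          ((za+zb) sin th + 2j(1-cos th)) / ((za+zb) cos th + j(1+za zb) sin th)]

for arbitrary face loads za, zb — the two circuits are exactly equivalent, and
the test suite checks this model against an independent Mason three-port
solve.

Transmit transfer: source Vs behind Rs drives a mid-line force
``F = phi * I * (Zleft || Zright)`` which propagates through the front
half-line and matching layers into the front load.  For fixed terminations
the receive transfer (incident force to receiver voltage, radiation condition
``F - Zf*u = 2*F_inc``) is exactly proportional, ``Hr = (2 Rs / Zf) * Ht``
(network reciprocity), so the two-way pulse-echo spectrum is ``Ht * Hr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .materials import MATERIALS, MaterialSpec, get_material

__all__ = [
    "EPS0",
    "Layer",
    "LayerStack",
    "BandMetrics",
    "KlmResponse",
    "tut_design_stack",
    "design_thickness",
    "klm_two_way_response",
    "extract_band_metrics",
    "default_frequency_grid",
]

EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class Layer:
    material: MaterialSpec
    thickness: float  # m

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")


@dataclass(frozen=True)
class LayerStack:
    """Piezo plate plus front matching layers, backing and face loads.

    ``front_layers`` are ordered from the piezo outward.  ``backing`` with
    ``backing_thickness=None`` is treated as a semi-infinite load (the
    default for the thick, lossy optical-epoxy backing); a finite thickness
    models it as one more transmission line terminated by ``back_load``.
    """

    piezo: MaterialSpec
    piezo_thickness: float
    area: float
    front_layers: tuple = ()
    backing: MaterialSpec = MATERIALS["epoxy"]
    backing_thickness: float | None = None
    front_load: MaterialSpec = MATERIALS["water"]
    back_load: MaterialSpec = MATERIALS["air"]

    def __post_init__(self) -> None:
        if not self.piezo.is_piezo:
            raise ValueError("piezo material needs kt and clamped_permittivity")
        if self.piezo_thickness <= 0 or self.area <= 0:
            raise ValueError("piezo thickness and area must be > 0")
        if self.backing_thickness is not None and self.backing_thickness <= 0:
            raise ValueError("backing_thickness must be > 0 or None")
        object.__setattr__(self, "front_layers", tuple(self.front_layers))

    def scaled(self, s: float) -> "LayerStack":
        """Geometric scaling: thicknesses by ``s``, area by ``s**2``.

        This scales the response in frequency by exactly 1/s (with the area
        scaled too, the electrical port impedances are frequency-invariant,
        so the shape is preserved even against a fixed source resistance).
        """
        return LayerStack(
            piezo=self.piezo,
            piezo_thickness=self.piezo_thickness * s,
            area=self.area * s**2,
            front_layers=tuple(Layer(l.material, l.thickness * s) for l in self.front_layers),
            backing=self.backing,
            backing_thickness=None if self.backing_thickness is None else self.backing_thickness * s,
            front_load=self.front_load,
            back_load=self.back_load,
        )


def tut_design_stack(
    materials: dict[str, MaterialSpec] | None = None,
    backing_semi_infinite: bool = True,
) -> LayerStack:
    """The transparent-transducer design stack: 94 um LNO, 30 um silica-epoxy
    composite, 19 um epoxy second matching, epoxy backing (nominally 1 mm),
    water front load.

    The backing defaults to a semi-infinite epoxy load: over the ~67
    round-trip wavelengths of the nominal 1-mm backing, real optical epoxy is
    strongly attenuating, so it behaves anechoically; a lossless finite line
    would instead imprint an unphysical comb of backing resonances.
    """
    m = dict(MATERIALS)
    if materials:
        m.update(materials)
    return LayerStack(
        piezo=m["lno_36y"],
        piezo_thickness=94e-6,
        area=36e-6,
        front_layers=(
            Layer(m["silica_epoxy_composite"], 30e-6),
            Layer(m["epoxy"], 19e-6),
        ),
        backing=m["epoxy"],
        backing_thickness=None if backing_semi_infinite else 1000e-6,
        front_load=m["water"],
        back_load=m["air"],
    )


def design_thickness(material: MaterialSpec, role: str, frequency: float) -> float:
    """Half- or quarter-wave layer thickness at ``frequency``."""
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    wavelength = material.longitudinal_velocity / frequency
    if role == "half_wave":
        return wavelength / 2.0
    if role == "quarter_wave":
        return wavelength / 4.0
    raise ValueError(f"unknown design role: {role!r}")


def default_frequency_grid(n: int = 4096, f_max: float = 150e6) -> np.ndarray:
    """Uniform grid 0..f_max (inclusive of 0, where the response is zero)."""
    return np.linspace(0.0, f_max, n)


def _complex_phase(material: MaterialSpec, thickness: float, f: np.ndarray) -> np.ndarray:
    """Propagation phase omega*l/v, minus j * attenuation when enabled."""
    phase = 2.0 * np.pi * f * thickness / material.longitudinal_velocity
    if material.attenuation_db_mhz_cm:
        np_per_m = (
            material.attenuation_db_mhz_cm * (f / 1e6) / 0.01 / 8.685889638065035
        )
        phase = phase - 1j * np_per_m * thickness
    return phase


def _cascade_front(stack: LayerStack, f: np.ndarray):
    """ABCD of front half piezo line + matching layers (center tap -> load plane)."""
    A = np.ones_like(f, dtype=complex)
    B = np.zeros_like(f, dtype=complex)
    C = np.zeros_like(f, dtype=complex)
    D = np.ones_like(f, dtype=complex)

    def push(z0, phi):
        nonlocal A, B, C, D
        c, s = np.cos(phi), np.sin(phi)
        A, B, C, D = (
            A * c + B * (1j * s / z0),
            A * (1j * z0 * s) + B * c,
            C * c + D * (1j * s / z0),
            C * (1j * z0 * s) + D * c,
        )

    zc = stack.piezo.acoustic_impedance * stack.area
    push(zc, _complex_phase(stack.piezo, stack.piezo_thickness / 2.0, f))
    for layer in stack.front_layers:
        push(layer.material.acoustic_impedance * stack.area, _complex_phase(layer.material, layer.thickness, f))
    return A, B, C, D


def _line_input_impedance(z0, phi, z_term):
    """Input impedance of a line of impedance z0, phase phi, terminated by z_term."""
    c, s = np.cos(phi), np.sin(phi)
    return z0 * (z_term * c + 1j * z0 * s) / (z0 * c + 1j * z_term * s)


@dataclass
class KlmResponse:
    """Frequency- and time-domain pulse-echo response of a stack."""

    frequencies: np.ndarray
    one_way: np.ndarray  # transmit transfer Ht (complex)
    two_way: np.ndarray  # pulse-echo spectrum Ht*Hr (complex)
    waveform: np.ndarray  # time-domain pulse-echo (real)
    dt: float  # waveform sample spacing, s

    def spectrum_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.frequencies, np.abs(self.two_way)]),
            delimiter=",",
            header="frequency_hz,two_way_magnitude",
            comments="",
        )

    def waveform_csv(self, path) -> None:
        t = np.arange(len(self.waveform)) * self.dt
        np.savetxt(
            path,
            np.column_stack([t, self.waveform]),
            delimiter=",",
            header="time_s,amplitude",
            comments="",
        )


def klm_two_way_response(
    stack: LayerStack,
    freq_grid: np.ndarray | None = None,
    source_impedance: float = 50.0,
) -> KlmResponse:
    """Pulse-echo (two-way) transfer of the stack on a uniform frequency grid.

    The transmit transfer Ht(f) is the force delivered to the front load per
    source volt behind ``source_impedance``; the receive transfer is
    ``(2*Rs/Zf) * Ht`` by reciprocity, and the two-way spectrum is their
    product.  The time-domain waveform is the inverse real FFT of the two-way
    spectrum (zero-phase reference at the grid origin).

    Raises a specification error for a non-uniform grid or zero-thickness
    layer (the latter is enforced at stack construction).
    """
    if freq_grid is None:
        freq_grid = default_frequency_grid()
    f = np.asarray(freq_grid, dtype=float)
    if f.ndim != 1 or len(f) < 8:
        raise ValueError("freq_grid must be a 1-D array with at least 8 points")
    df = np.diff(f)
    if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6):
        raise ValueError("freq_grid must be uniform and increasing")
    if f[0] < 0:
        raise ValueError("freq_grid must be non-negative")

    # avoid the w=0 singularities; patch the DC bin afterwards
    fz = f.copy()
    zero = fz == 0.0
    fz[zero] = max(df[0] * 1e-3, 1.0)

    w = 2.0 * np.pi * fz
    piezo = stack.piezo
    d = stack.piezo_thickness
    area = stack.area
    v = piezo.longitudinal_velocity
    zc = piezo.acoustic_impedance * area
    c0 = piezo.clamped_permittivity * EPS0 * area / d
    w0 = np.pi * v / d
    theta = _complex_phase(piezo, d, fz)

    # back branch: half piezo line into the backing
    zb_load = stack.backing.acoustic_impedance * area
    if stack.backing_thickness is not None:
        zb_load = _line_input_impedance(
            zb_load,
            _complex_phase(stack.backing, stack.backing_thickness, fz),
            stack.back_load.acoustic_impedance * area,
        )
    z_left = _line_input_impedance(zc, theta / 2.0, zb_load)

    # front branch: half piezo line + matching layers into the front load
    A, B, C, D = _cascade_front(stack, fz)
    zf = stack.front_load.acoustic_impedance * area
    z_right = (A * zf + B) / (C * zf + D)

    z_parallel = z_left * z_right / (z_left + z_right)
    half = theta / 2.0
    phi = piezo.kt * np.sqrt(np.pi / (w0 * c0 * zc)) * np.sin(half) / half
    x1 = piezo.kt**2 * np.sin(theta) / (theta * w * c0)
    z_in = 1.0 / (1j * w * c0) + 1j * x1 + phi**2 * z_parallel

    current = 1.0 / (source_impedance + z_in)
    f_center = phi * current * z_parallel
    # propagate the center-tap force through the front cascade into the load
    h_t = zf * f_center / ((A * zf + B))
    h_t[zero] = 0.0

    h_r = (2.0 * source_impedance / zf) * h_t
    two_way = h_t * h_r

    spectrum = two_way.copy()
    spectrum[zero] = 0.0
    waveform = np.fft.irfft(spectrum)
    dt = 1.0 / (2.0 * (len(f) - 1) * df[0])
    return KlmResponse(f, h_t, two_way, waveform, dt)


@dataclass(frozen=True)
class BandMetrics:
    """-6 dB band summary of a magnitude spectrum."""

    center_frequency: float
    fractional_bandwidth: float
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.center_frequency < self.f_high:
            raise ValueError("band metrics require f_low < fc < f_high")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "center_frequency_hz": self.center_frequency,
                    "fractional_bandwidth": self.fractional_bandwidth,
                    "f_low_hz": self.f_low,
                    "f_high_hz": self.f_high,
                },
                fh,
                indent=2,
            )


def extract_band_metrics(frequencies: np.ndarray, magnitude: np.ndarray) -> BandMetrics:
    """-6 dB center frequency and fractional bandwidth of a magnitude spectrum.

    ``f_low``/``f_high`` are the outermost crossings of ``max - 6 dB`` around
    the global peak, located by linear interpolation between grid points;
    ``fc = (f_low + f_high)/2`` and the fractional bandwidth is
    ``(f_high - f_low)/fc``.  Raises a bandwidth-undefined error when the
    -6 dB level is never crossed inside the grid.
    """
    f = np.asarray(frequencies, dtype=float)
    mag = np.asarray(magnitude, dtype=float)
    if f.shape != mag.shape or f.ndim != 1:
        raise ValueError("frequencies and magnitude must be matching 1-D arrays")
    peak = int(np.argmax(mag))
    level = mag[peak] * 10.0 ** (-6.0 / 20.0)

    below_left = np.where(mag[: peak + 1] < level)[0]
    below_right = np.where(mag[peak:] < level)[0]
    if len(below_left) == 0 or len(below_right) == 0:
        raise ValueError("-6 dB level never crossed within the frequency grid")

    i = below_left[-1]  # last sub-level point left of the peak
    f_low = f[i] + (f[i + 1] - f[i]) * (level - mag[i]) / (mag[i + 1] - mag[i])
    j = peak + below_right[0] - 1  # last above-level point right of the peak
    f_high = f[j] + (f[j + 1] - f[j]) * (level - mag[j]) / (mag[j + 1] - mag[j])

    fc = 0.5 * (f_low + f_high)
    return BandMetrics(fc, (f_high - f_low) / fc, f_low, f_high)
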