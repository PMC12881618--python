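"""Synthetic photoacoustic acquisition: per-trigger A-scans from a phantom.

Forward model: at each laser shot the focused beam deposits energy along a
lateral Gaussian column through the phantom; the generated initial pressure
at depth z arrives at the transducer after a one-way flight t = z/c (a
photoacoustic reception, unlike the transducer's pulse-echo characterization),
is convolved with the transducer's two-way impulse waveform, sampled at the
digitizer rate, and perturbed with seeded white Gaussian noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantoms import Phantom
from .scanner import Trajectory
from .triggers import PrfSchedule, trigger_train

__all__ = ["AcquisitionSettings", "AScan", "SampleSet", "simulate_ascan", "acquire"]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Digitizer and beam settings.

    ``sampling_rate`` in Hz (250 MHz digitizer default), ``speed_of_sound``
    in m/s, ``focal_spot_sigma`` the lateral Gaussian beam sigma in m,
    ``noise_sigma`` additive white noise std in the same relative units as
    the absorption grid.
    """

    sampling_rate: float = 250e6
    speed_of_sound: float = 1500.0
    record_length: int = 256
    focal_spot_sigma: float = 3e-6
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.speed_of_sound <= 0:
            raise ValueError("sampling_rate and speed_of_sound must be > 0")
        if self.record_length <= 0:
            raise ValueError("record_length must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def depth_sample_size(self) -> float:
        """Depth covered by one sample for one-way flight, c / fs (m)."""
        return self.speed_of_sound / self.sampling_rate

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "speed_of_sound": self.speed_of_sound,
            "record_length": self.record_length,
            "focal_spot_sigma": self.focal_spot_sigma,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSettings":
        return cls(**d)


@dataclass
class AScan:
    """One depth-resolved record (relative pressure units)."""

    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AScan samples must be 1-D")


@dataclass
class SampleSet:
    """Scattered acquisition: per-shot beam positions and A-scans, fire-ordered."""

    positions: np.ndarray  # (N, 2) m
    ascans: np.ndarray  # (N, record_length)
    settings: AcquisitionSettings

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.ascans = np.asarray(self.ascans, dtype=float)
        if len(self.positions) != len(self.ascans):
            raise ValueError("positions and ascans must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def save(self, prefix) -> None:
        """Binary array of A-scans + CSV positions + JSON settings."""
        np.save(str(prefix) + "_ascans.npy", self.ascans)
        np.savetxt(
            str(prefix) + "_positions.csv",
            self.positions,
            delimiter=",",
            header="x_m,y_m",
            comments="",
        )
        with open(str(prefix) + "_settings.json", "w") as fh:
            json.dump(self.settings.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, prefix) -> "SampleSet":
        ascans = np.load(str(prefix) + "_ascans.npy")
        positions = np.loadtxt(str(prefix) + "_positions.csv", delimiter=",", skiprows=1)
        with open(str(prefix) + "_settings.json") as fh:
            settings = AcquisitionSettings.from_dict(json.load(fh))
        return cls(positions, ascans, settings)


def _depth_profile(phantom: Phantom, beam_xy, sigma: float) -> np.ndarray:
    """Laterally Gaussian-weighted absorption sum along z."""
    (x0, x1), (y0, y1) = phantom.lateral_extent()
    bx, by = float(beam_xy[0]), float(beam_xy[1])
    if not (x0 - 1e-12 <= bx <= x1 + 1e-12 and y0 - 1e-12 <= by <= y1 + 1e-12):
        raise ValueError("beam position outside phantom lateral extent")
    dx, dy, _ = phantom.voxel_size
    nx, ny, nz = phantom.shape
    cut = 4.0 * sigma
    ix0 = max(int(np.floor((bx - phantom.origin[0] - cut) / dx)), 0)
    ix1 = min(int(np.ceil((bx - phantom.origin[0] + cut) / dx)) + 1, nx)
    iy0 = max(int(np.floor((by - phantom.origin[1] - cut) / dy)), 0)
    iy1 = min(int(np.ceil((by - phantom.origin[1] + cut) / dy)) + 1, ny)
    if ix0 >= ix1 or iy0 >= iy1:
        return np.zeros(nz)
    xs = phantom.origin[0] + np.arange(ix0, ix1) * dx
    ys = phantom.origin[1] + np.arange(iy0, iy1) * dy
    wx = np.exp(-((xs - bx) ** 2) / (2.0 * sigma * sigma))
    wy = np.exp(-((ys - by) ** 2) / (2.0 * sigma * sigma))
    w = wx[:, None] * wy[None, :]
    block = phantom.absorption[ix0:ix1, iy0:iy1, :]
    return np.tensordot(w, block, axes=([0, 1], [0, 1]))


def simulate_ascan(
    phantom: Phantom,
    beam_xy,
    impulse: np.ndarray,
    settings: AcquisitionSettings,
    rng: np.random.Generator | None = None,
) -> AScan:
    """One A-scan at a beam position.

    The initial-pressure depth line is mapped to arrival times t = z/c,
    accumulated at the nearest digitizer sample, convolved with ``impulse``
    (whose index 0 is its time reference, sampled at ``settings.sampling_rate``)
    and truncated to ``record_length``.  Emits a truncation warning when the
    deepest absorber falls past the end of the record.
    """
    p_z = _depth_profile(phantom, beam_xy, settings.focal_spot_sigma)
    fs = settings.sampling_rate
    c = settings.speed_of_sound
    oz = phantom.origin[2]
    dz = phantom.voxel_size[2]

    record = np.zeros(settings.record_length)
    nz = len(p_z)
    z = oz + np.arange(nz) * dz
    idx = np.round(z / c * fs).astype(int)
    nonzero = p_z > 0
    if nonzero.any() and idx[nonzero].max() >= settings.record_length:
        warnings.warn(
            "record too short to hold the deepest absorber; A-scan truncated",
            stacklevel=2,
        )
    keep = nonzero & (idx >= 0) & (idx < settings.record_length)
    np.add.at(record, idx[keep], p_z[keep])

    impulse = np.asarray(impulse, dtype=float)
    record = np.convolve(record, impulse)[: settings.record_length]

    if settings.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(settings.seed)
        record = record + rng.normal(0.0, settings.noise_sigma, settings.record_length)
    return AScan(record, t0=0.0)


def acquire(
    trajectory: Trajectory,
    schedule: PrfSchedule,
    phantom: Phantom,
    impulse: np.ndarray,
    settings: AcquisitionSettings,
) -> SampleSet:
    """Evaluate :func:`simulate_ascan` at every fire position.

    Deterministic under ``settings.seed``: one generator is created up front
    and consumed shot by shot in fire order.
    """
    train = trigger_train(trajectory, schedule)
    rng = np.random.default_rng(settings.seed)
    ascans = np.empty((len(train.fire_times), settings.record_length))
    for i, pos in enumerate(train.fire_positions):
        ascans[i] = simulate_ascan(phantom, pos, impulse, settings, rng=rng).samples
    return SampleSet(train.fire_positions, ascans, settings)
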