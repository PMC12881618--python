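"""Stepped-PRF laser trigger plans, shot-density maps, and fill-factor analysis.

A resonant spiral scan sweeps slowly near the center and fast at the rim, so a
fixed laser pulse-repetition frequency (PRF) piles shots onto the central
pixels.  Stepping the PRF up as the spiral opens equalizes the areal
illumination density; the reference plan used here steps through
20/100/200/250/500 kHz over the 1-s imaging ramp, leaving the laser off for
the first 50 ms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .gridding import fov_disc_mask, position_to_pixel
from .scanner import ScanProtocol, Trajectory, simulate_trajectory

__all__ = [
    "PrfStep",
    "PrfSchedule",
    "TriggerTrain",
    "DensityMap",
    "reference_schedule",
    "fire_times",
    "trigger_train",
    "density_map",
    "visited_mask",
    "fill_factor",
    "frequency_sweep",
]

DEFAULT_GRID_SIZE = 512
DEFAULT_FOV_DIAMETER = 2.6e-3


@dataclass(frozen=True)
class PrfStep:
    """One constant-rate firing interval: [t_start, t_end) at ``prf`` Hz."""

    t_start: float
    t_end: float
    prf: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("PrfStep requires t_start < t_end")
        if self.prf <= 0:
            raise ValueError("PrfStep requires prf > 0")

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass(frozen=True)
class PrfSchedule:
    """Ordered, non-overlapping sequence of PRF steps; gaps mean laser off."""

    steps: tuple

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        for a, b in zip(steps, steps[1:]):
            if b.t_start < a.t_end:
                raise ValueError("PrfSchedule steps must be ordered and non-overlapping")

    @property
    def span(self) -> tuple:
        if not self.steps:
            return (0.0, 0.0)
        return (self.steps[0].t_start, self.steps[-1].t_end)

    def step_containing(self, t: float):
        for s in self.steps:
            if s.contains(t):
                return s
        return None

    def to_dict(self) -> dict:
        return {"steps": [[s.t_start, s.t_end, s.prf] for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PrfSchedule":
        return cls(tuple(PrfStep(*row) for row in d["steps"]))

    def scaled_prf(self, factor: float) -> "PrfSchedule":
        """Same intervals with every PRF multiplied by ``factor`` (desk-scale runs)."""
        return PrfSchedule(
            tuple(PrfStep(s.t_start, s.t_end, s.prf * factor) for s in self.steps)
        )


def reference_schedule() -> PrfSchedule:
    """The handheld probe's stepped PRF plan for the 1-s imaging ramp.

    20 kHz on 0.05-0.1 s, 100 kHz on 0.1-0.2 s, 200 kHz on 0.2-0.3 s,
    250 kHz on 0.3-0.4 s, and 500 kHz on 0.4-1 s; laser off on [0, 0.05) s.
    """
    return PrfSchedule(
        (
            PrfStep(0.05, 0.1, 20e3),
            PrfStep(0.1, 0.2, 100e3),
            PrfStep(0.2, 0.3, 200e3),
            PrfStep(0.3, 0.4, 250e3),
            PrfStep(0.4, 1.0, 500e3),
        )
    )


def fire_times(schedule: PrfSchedule) -> np.ndarray:
    """Laser firing timestamps: uniform 1/prf spacing from each step's start.

    Per-step pulse count is floor(duration * prf), evaluated with a small
    epsilon so exact-integer products are not lost to binary rounding.
    """
    parts = []
    for s in schedule.steps:
        n = int(np.floor((s.t_end - s.t_start) * s.prf + 1e-9))
        parts.append(s.t_start + np.arange(n) / s.prf)
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


@dataclass
class TriggerTrain:
    """Firing times paired with interpolated beam positions."""

    fire_times: np.ndarray
    fire_positions: np.ndarray

    def __post_init__(self) -> None:
        self.fire_times = np.asarray(self.fire_times, dtype=float)
        self.fire_positions = np.asarray(self.fire_positions, dtype=float)
        if len(self.fire_times) != len(self.fire_positions):
            raise ValueError("fire_times and fire_positions must pair up")
        if len(self.fire_times) > 1 and not np.all(np.diff(self.fire_times) > 0):
            raise ValueError("fire_times must be strictly increasing")


def trigger_train(trajectory: Trajectory, schedule: PrfSchedule) -> TriggerTrain:
    """Fire times from the schedule, positions by trajectory interpolation."""
    t = fire_times(schedule)
    return TriggerTrain(t, trajectory.interpolate(t))


@dataclass
class DensityMap:
    """Per-pixel laser-shot counts over the image grid."""

    grid: np.ndarray
    grid_size: int
    fov_diameter: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.shape != (self.grid_size, self.grid_size):
            raise ValueError("grid shape inconsistent with grid_size")
        if np.any(self.grid < 0):
            raise ValueError("shot counts must be non-negative")

    def summary(self) -> dict:
        disc = fov_disc_mask(self.grid_size, self.fov_diameter)
        return {
            "min": int(self.grid.min()),
            "max": int(self.grid.max()),
            "mean": float(self.grid.mean()),
            "total": int(self.grid.sum()),
            "fill_factor": fill_factor(self),
            "disc_pixels": int(disc.sum()),
        }

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.clip(self.grid, 0, 65535).astype(np.uint16))

    def summary_csv(self, path) -> None:
        s = self.summary()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(list(s))
            w.writerow([s[k] for k in s])


def density_map(
    trajectory: Trajectory,
    schedule: PrfSchedule,
    grid_size: int = DEFAULT_GRID_SIZE,
    fov_diameter: float = DEFAULT_FOV_DIAMETER,
) -> DensityMap:
    """Bin per-trigger beam positions onto the image grid.

    Fire times are mapped to positions by linear interpolation of the
    trajectory and binned with the same pixel-assignment rule the
    reconstruction uses (:func:`spiralpam.gridding.position_to_pixel`).
    Raises a range error when a fire time falls outside the trajectory span.
    """
    train = trigger_train(trajectory, schedule)
    counts = np.zeros(grid_size * grid_size, dtype=np.int64)
    if len(train.fire_times):
        idx, ok = position_to_pixel(train.fire_positions, grid_size, fov_diameter)
        flat = idx[ok, 0] * grid_size + idx[ok, 1]
        counts += np.bincount(flat, minlength=grid_size * grid_size)
    return DensityMap(counts.reshape(grid_size, grid_size), grid_size, fov_diameter)


def visited_mask(
    trajectory: Trajectory,
    schedule: PrfSchedule,
    grid_size: int = DEFAULT_GRID_SIZE,
    fov_diameter: float = DEFAULT_FOV_DIAMETER,
    oversample_rate: float = 5e6,
) -> np.ndarray:
    """Pixels traversed by the beam path while the laser is on.

    The trajectory is resampled at ``oversample_rate`` inside every PRF step
    so that consecutive path samples move by well under one pixel; each sample
    is assigned a pixel with the shared rule.
    """
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for s in schedule.steps:
        t = np.arange(s.t_start, s.t_end, 1.0 / oversample_rate)
        pos = trajectory.interpolate(t)
        idx, ok = position_to_pixel(pos, grid_size, fov_diameter)
        mask[idx[ok, 0], idx[ok, 1]] = True
    return mask


def fill_factor(dmap: DensityMap, mask: np.ndarray | None = None) -> float:
    """Fraction of pixels with at least one shot.

    By default the fraction is taken over pixels inside the FOV disc; pass
    ``mask`` (e.g. a :func:`visited_mask`) to restrict to another region.
    """
    if mask is None:
        mask = fov_disc_mask(dmap.grid_size, dmap.fov_diameter)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    return float((dmap.grid[mask] >= 1).sum() / n)


def frequency_sweep(
    fixed_prf: float,
    frequencies,
    protocol_template: ScanProtocol | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    fov_diameter: float = DEFAULT_FOV_DIAMETER,
    sample_rate: float | None = None,
) -> np.ndarray:
    """Fill factor versus scan frequency at a fixed PRF.

    Re-runs the kinematic spiral for each candidate scan frequency with every
    other protocol setting held fixed and a single firing interval spanning
    the imaging phase; reproduces the aliasing analysis in which degenerate
    PRF/frequency ratios leave systematic gaps.
    """
    if fixed_prf <= 0:
        raise ValueError("fixed_prf must be > 0")
    if protocol_template is None:
        protocol_template = ScanProtocol()
    out = []
    for f in frequencies:
        proto = ScanProtocol(
            scan_frequency=float(f),
            imaging_duration=protocol_template.imaging_duration,
            braking_duration=0.0,
            decay_duration=0.0,
            max_radius=protocol_template.max_radius,
            ramp_shape=protocol_template.ramp_shape,
        )
        sr = sample_rate or max(2 * fixed_prf, 20 * float(f))
        traj = simulate_trajectory(proto, sample_rate=sr)
        sched = PrfSchedule((PrfStep(0.0, proto.imaging_duration, fixed_prf),))
        dmap = density_map(traj, sched, grid_size, fov_diameter)
        out.append(fill_factor(dmap))
    return np.asarray(out)
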