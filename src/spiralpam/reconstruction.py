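"""Scattered-sample volume reconstruction and projection images.

Position-tagged A-scans are assigned to a regular grid by a three-case rule:
a pixel holding exactly one sample takes that trace verbatim; a pixel holding
several takes their element-wise mean; an empty pixel inside the field of
view receives an inverse-distance-weighted combination of the nearest
directly-hit pixels' traces.  Envelope, maximum-amplitude-projection (MAP)
and depth-encoded images derive from the assembled volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import cKDTree

from .acquisition import AScan, SampleSet
from .gridding import fov_disc_mask, pixel_centers, pixel_pitch, position_to_pixel

__all__ = [
    "Volume",
    "MapImage",
    "position_to_pixel",
    "grid_assign",
    "envelope",
    "map_projection",
    "depth_encode",
]


@dataclass
class Volume:
    """Regular image grid of traces: (x-pixel, y-pixel, depth-sample)."""

    data: np.ndarray
    pixel_size: float  # m
    depth_sample_size: float  # m per depth sample (one-way, c/fs)
    fov_diameter: float  # m
    fill_mask: np.ndarray  # (grid, grid) bool: directly-hit pixels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def grid_size(self) -> int:
        return self.data.shape[0]

    def save(self, tiff_path, meta_path=None) -> None:
        import tifffile

        tifffile.imwrite(tiff_path, np.moveaxis(self.data.astype(np.float32), 2, 0))
        if meta_path is None:
            meta_path = str(tiff_path) + ".json"
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "pixel_size": self.pixel_size,
                    "depth_sample_size": self.depth_sample_size,
                    "fov_diameter": self.fov_diameter,
                },
                fh,
                indent=2,
            )


@dataclass
class MapImage:
    """2-D projection image: MAP amplitudes or depth indices."""

    data: np.ndarray
    provenance: str  # "map" | "depth"
    pixel_size: float = 0.0
    background: np.ndarray | None = None  # for depth images

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("MapImage data must be 2-D")
        if self.provenance not in ("map", "depth"):
            raise ValueError("provenance must be 'map' or 'depth'")

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))


def grid_assign(
    samples: SampleSet,
    grid_size: int,
    fov_diameter: float,
    k_neighbors: int = 4,
    power: float = 1.0,
) -> Volume:
    """Assemble scattered (position, A-scan) samples into a Volume.

    Case 1: a pixel with exactly one sample takes that A-scan directly.
    Case 2: a pixel with k > 1 samples takes the element-wise mean.
    Case 3: an empty pixel inside the FOV disc takes an inverse-distance-
    weighted (weights ~ d^-power over ``k_neighbors`` nearest directly-hit
    pixel centers) combination of whole traces.  Pixels outside the disc stay
    zero.  ``fill_mask`` records the case-1/2 pixels.

    Raises a reconstruction error when no sample lands inside the grid.
    """
    if len(samples) == 0:
        raise ValueError("cannot reconstruct from an empty SampleSet")
    record = samples.ascans.shape[1]
    idx, ok = position_to_pixel(samples.positions, grid_size, fov_diameter)
    if not ok.any():
        raise ValueError("no directly-hit pixels: all samples fall outside the grid")
    flat = idx[ok, 0] * grid_size + idx[ok, 1]
    traces = samples.ascans[ok]

    sums = np.zeros((grid_size * grid_size, record))
    np.add.at(sums, flat, traces)
    counts = np.bincount(flat, minlength=grid_size * grid_size)

    filled = counts > 0
    data = np.zeros((grid_size * grid_size, record))
    data[filled] = sums[filled] / counts[filled, None]

    disc = fov_disc_mask(grid_size, fov_diameter).ravel()
    empty = disc & ~filled
    if empty.any():
        centers = pixel_centers(grid_size, fov_diameter)
        xx, yy = np.meshgrid(centers, centers, indexing="ij")
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        tree = cKDTree(coords[filled])
        k = min(k_neighbors, int(filled.sum()))
        dist, nbr = tree.query(coords[empty], k=k)
        dist = np.atleast_2d(dist.reshape(len(dist), -1))
        nbr = np.atleast_2d(nbr.reshape(len(nbr), -1))
        w = 1.0 / np.maximum(dist, 1e-30) ** power
        w /= w.sum(axis=1, keepdims=True)
        filled_traces = data[filled]
        data[empty] = np.einsum("ik,ikr->ir", w, filled_traces[nbr])

    settings = samples.settings
    return Volume(
        data=data.reshape(grid_size, grid_size, record),
        pixel_size=pixel_pitch(grid_size, fov_diameter),
        depth_sample_size=settings.speed_of_sound / settings.sampling_rate,
        fov_diameter=fov_diameter,
        fill_mask=filled.reshape(grid_size, grid_size),
    )


def envelope(signal) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert-transform envelope).

    Accepts an :class:`AScan`, a 1-D array, or an N-D array (envelope along
    the last axis).
    """
    x = signal.samples if isinstance(signal, AScan) else np.asarray(signal, dtype=float)
    return np.abs(hilbert(x, axis=-1))


def map_projection(volume: Volume) -> MapImage:
    """Maximum amplitude projection: per-pixel max of the envelope along depth."""
    env = envelope(volume.data)
    return MapImage(env.max(axis=-1), "map", pixel_size=volume.pixel_size)


def depth_encode(volume: Volume, amplitude_floor: float = 0.05) -> MapImage:
    """Per-pixel depth index of the envelope maximum.

    Pixels whose peak envelope falls below ``amplitude_floor`` times the
    global peak are marked background (flagged in ``background`` and set to
    -1 in ``data``).
    """
    env = envelope(volume.data)
    peak = env.max(axis=-1)
    depth = env.argmax(axis=-1).astype(np.int64)
    gmax = peak.max()
    background = peak < amplitude_floor * gmax if gmax > 0 else np.ones_like(peak, bool)
    depth[background] = -1
    return MapImage(depth, "depth", pixel_size=volume.pixel_size, background=background)
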