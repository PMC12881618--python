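"""Shared position-to-pixel mapping for the density map and reconstruction.

One affine convention is used everywhere: pixel center 0 sits at -FOV/2,
pixel center ``grid_size - 1`` at +FOV/2, so the pixel pitch is
``fov_diameter / (grid_size - 1)``.  Continuous indices are rounded
half-away-from-zero (the documented tie-break).
"""

from __future__ import annotations

import numpy as np

__all__ = ["position_to_pixel", "pixel_pitch", "pixel_centers", "fov_disc_mask"]


def pixel_pitch(grid_size: int, fov_diameter: float) -> float:
    """Physical spacing between adjacent pixel centers (m)."""
    return fov_diameter / (grid_size - 1)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def position_to_pixel(
    positions: np.ndarray, grid_size: int, fov_diameter: float
):
    """Map planar positions (m) to integer pixel indices.

    Returns ``(indices, in_grid)`` where ``indices`` is (N, 2) int and
    ``in_grid`` flags positions that landed inside the grid.  Out-of-grid
    positions are flagged, never raised on.
    """
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    cont = (p + fov_diameter / 2.0) * ((grid_size - 1) / fov_diameter)
    idx = _round_half_away(cont).astype(np.int64)
    in_grid = np.all((idx >= 0) & (idx < grid_size), axis=1)
    return idx, in_grid


def pixel_centers(grid_size: int, fov_diameter: float) -> np.ndarray:
    """1-D array of pixel-center coordinates along one axis (m)."""
    return -fov_diameter / 2.0 + np.arange(grid_size) * pixel_pitch(grid_size, fov_diameter)


def fov_disc_mask(grid_size: int, fov_diameter: float) -> np.ndarray:
    """Boolean (grid, grid) mask of pixels whose centers lie in the FOV disc."""
    c = pixel_centers(grid_size, fov_diameter)
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return np.hypot(xx, yy) <= fov_diameter / 2.0 + 1e-15
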