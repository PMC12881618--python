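"""Procedural test objects: vessel trees, edge/grid/point targets.

All phantoms are non-negative absorption grids in [0, 1] on a regular voxel
lattice.  Convention: axis 0 and 1 are the lateral scan plane (x, y); axis 2
is the acoustic axis z, increasing away from the probe.  Voxel (0,0,0) center
sits at ``origin``; generators are deterministic under their seed and record
enough ground truth (centerlines, diameters, edge position) in ``meta`` to
score reconstruction and quantification against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Phantom",
    "VesselTreeParams",
    "make_vessel_phantom",
    "make_edge_target",
    "make_grid_target",
    "make_point_target",
]


@dataclass
class Phantom:
    absorption: np.ndarray  # (nx, ny, nz), values in [0, 1]
    voxel_size: tuple  # (dx, dy, dz) m
    origin: tuple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorption = np.asarray(self.absorption, dtype=np.float32)
        if self.absorption.ndim != 3:
            raise ValueError("absorption must be a 3-D grid")
        if self.absorption.min() < 0 or self.absorption.max() > 1 + 1e-6:
            raise ValueError("absorption values must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")

    @property
    def shape(self):
        return self.absorption.shape

    def lateral_extent(self):
        """((xmin, xmax), (ymin, ymax)) physical bounds of voxel centers."""
        nx, ny, _ = self.shape
        dx, dy, _ = self.voxel_size
        ox, oy, _ = self.origin
        return (ox, ox + (nx - 1) * dx), (oy, oy + (ny - 1) * dy)

    def save(self, tiff_path, meta_path=None) -> None:
        """Multi-page TIFF (z pages) plus a JSON sidecar with geometry/meta."""
        import tifffile

        tifffile.imwrite(tiff_path, np.moveaxis(self.absorption, 2, 0))
        if meta_path is None:
            meta_path = str(tiff_path) + ".json"
        side = {
            "voxel_size": list(self.voxel_size),
            "origin": list(self.origin),
            "meta": _jsonable(self.meta),
        }
        with open(meta_path, "w") as fh:
            json.dump(side, fh, indent=2)

    @classmethod
    def load(cls, tiff_path, meta_path=None) -> "Phantom":
        import tifffile

        data = np.moveaxis(tifffile.imread(tiff_path), 0, 2)
        if meta_path is None:
            meta_path = str(tiff_path) + ".json"
        with open(meta_path) as fh:
            side = json.load(fh)
        return cls(data, tuple(side["voxel_size"]), tuple(side["origin"]), side["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class VesselTreeParams:
    """Random-walk vessel tree controls.

    ``tortuosity`` is the per-step standard deviation of the in-plane heading
    perturbation (radians); ``branching_prob`` is the per-step probability of
    spawning a thinner side branch; ``depth_band`` bounds the tree's z extent
    in meters.
    """

    n_roots: int = 4
    diameter_range: tuple = (30e-6, 150e-6)
    tortuosity: float = 0.25
    branching_prob: float = 0.03
    depth_band: tuple = (100e-6, 400e-6)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not 0 < lo <= hi:
            raise ValueError("diameter_range must be positive and ordered")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must lie in [0, 1]")
        if self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")


def _rasterize_segments(absorption, segments, voxel_size):
    """Fill voxels within ``radius`` of each segment axis (filled cylinders)."""
    nx, ny, nz = absorption.shape
    vs = np.asarray(voxel_size)
    for p0, p1, radius in segments:
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        i0 = np.maximum(np.floor(lo / vs).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / vs).astype(int) + 1, [nx, ny, nz])
        if np.any(i0 >= i1):
            continue
        ax = (np.arange(i0[0], i1[0]) * vs[0])[:, None, None]
        ay = (np.arange(i0[1], i1[1]) * vs[1])[None, :, None]
        az = (np.arange(i0[2], i1[2]) * vs[2])[None, None, :]
        d = p1 - p0
        L2 = float(d @ d)
        rx, ry, rz = ax - p0[0], ay - p0[1], az - p0[2]
        if L2 > 0:
            t = (rx * d[0] + ry * d[1] + rz * d[2]) / L2
            t = np.clip(t, 0.0, 1.0)
        else:
            t = 0.0
        cx = rx - t * d[0]
        cy = ry - t * d[1]
        cz = rz - t * d[2]
        inside = cx * cx + cy * cy + cz * cz <= radius * radius
        absorption[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]][inside] = 1.0


def make_vessel_phantom(
    params: VesselTreeParams,
    shape=(96, 96, 32),
    voxel_size=(10e-6, 10e-6, 10e-6),
) -> Phantom:
    """Random-walk tube tree rasterized as filled cylinders.

    Roots start on one lateral edge and walk across the volume with smoothly
    perturbed headings; side branches inherit a reduced diameter.  Absorption
    is 1 inside vessels and 0 outside.  Ground-truth centerlines and
    per-segment diameters are stored in ``meta``; segments whose diameter
    falls below two voxels add a resolution warning to ``meta``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < m for s, m in zip(shape, (64, 64, 32))):
        raise ValueError("vessel phantom needs shape >= (64, 64, 32)")
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(voxel_size)
    extent = (np.asarray(shape) - 1) * vs
    step = 2.0 * float(vs[:2].min())

    absorption = np.zeros(shape, dtype=np.float32)
    segments = []
    centerlines = []
    diameters = []
    warnings = []

    lo_d, hi_d = params.diameter_range
    z_lo = max(params.depth_band[0], 0.0)
    z_hi = min(params.depth_band[1], extent[2])

    # walks: (position, heading, diameter)
    walks = []
    for _ in range(params.n_roots):
        start = np.array(
            [0.0, rng.uniform(0.1, 0.9) * extent[1], rng.uniform(z_lo, z_hi)]
        )
        walks.append((start, rng.uniform(-0.4, 0.4), rng.uniform(lo_d, hi_d)))

    max_steps = int(3 * extent[:2].max() / step)
    while walks:
        pos, heading, diam = walks.pop()
        radius = diam / 2.0
        if diam < 2.0 * vs[:2].min():
            warnings.append(
                f"vessel diameter {diam:.2e} m below 2 voxels; rasterization coarse"
            )
        line = [pos.copy()]
        for _ in range(max_steps):
            heading += rng.normal(0.0, params.tortuosity)
            dz = rng.normal(0.0, 0.15) * step
            new = pos + np.array(
                [np.cos(heading) * step, np.sin(heading) * step, dz]
            )
            new[2] = np.clip(new[2], z_lo, z_hi)
            if not (0 <= new[0] <= extent[0] and 0 <= new[1] <= extent[1]):
                break
            segments.append((pos.copy(), new.copy(), radius))
            line.append(new.copy())
            if (
                rng.random() < params.branching_prob
                and diam * 0.6 >= lo_d * 0.5
                and len(walks) < 64
            ):
                walks.append(
                    (new.copy(), heading + rng.choice([-1.0, 1.0]) * 0.8, diam * 0.6)
                )
            pos = new
        centerlines.append(np.asarray(line))
        diameters.append(diam)

    _rasterize_segments(absorption, segments, voxel_size)
    meta = {
        "generator": "vessel_tree",
        "params": {
            "n_roots": params.n_roots,
            "diameter_range": list(params.diameter_range),
            "tortuosity": params.tortuosity,
            "branching_prob": params.branching_prob,
            "depth_band": list(params.depth_band),
            "seed": params.seed,
        },
        "centerlines": [c.tolist() for c in centerlines],
        "diameters": diameters,
        "warnings": warnings,
    }
    return Phantom(absorption, tuple(voxel_size), meta=meta)


def make_edge_target(
    shape=(128, 128, 16),
    voxel_size=(5e-6, 5e-6, 10e-6),
    edge_axis: int = 0,
    depth: float = 50e-6,
) -> Phantom:
    """Thin absorbing half-plane with a sharp step across ``edge_axis``.

    The step sits exactly at the grid midline: voxels with index >= n/2 along
    the edge axis absorb, the rest are empty; the sheet occupies the single
    z slice nearest ``depth``.
    """
    if edge_axis not in (0, 1):
        raise ValueError("edge_axis must be 0 or 1")
    absorption = np.zeros(shape, dtype=np.float32)
    iz = int(round(depth / voxel_size[2]))
    iz = min(max(iz, 0), shape[2] - 1)
    half = shape[edge_axis] // 2
    if edge_axis == 0:
        absorption[half:, :, iz] = 1.0
    else:
        absorption[:, half:, iz] = 1.0
    meta = {"generator": "edge_target", "edge_axis": edge_axis, "edge_index": half, "depth_index": iz}
    return Phantom(absorption, tuple(voxel_size), meta=meta)


def make_grid_target(
    shape=(128, 128, 16),
    voxel_size=(5e-6, 5e-6, 10e-6),
    pitch: float = 100e-6,
    bar_width: float = 40e-6,
    depth: float = 50e-6,
) -> Phantom:
    """Periodic bars along both lateral axes at the stated pitch (film-target
    style grid pattern) in a single z slice."""
    pitch_vox = pitch / voxel_size[0]
    if pitch_vox < 2:
        raise ValueError("pitch below 2 voxels is unresolvable")
    bar_vox = max(int(round(bar_width / voxel_size[0])), 1)
    period = int(round(pitch_vox))
    absorption = np.zeros(shape, dtype=np.float32)
    iz = min(max(int(round(depth / voxel_size[2])), 0), shape[2] - 1)
    ix = np.arange(shape[0]) % period < bar_vox
    iy = np.arange(shape[1]) % period < bar_vox
    sheet = ix[:, None] | iy[None, :]
    absorption[:, :, iz] = sheet.astype(np.float32)
    meta = {
        "generator": "grid_target",
        "pitch_vox": period,
        "bar_vox": bar_vox,
        "depth_index": iz,
    }
    return Phantom(absorption, tuple(voxel_size), meta=meta)


def make_point_target(
    shape=(64, 64, 64),
    voxel_size=(5e-6, 5e-6, 5e-6),
    positions=((32, 32, 32),),
) -> Phantom:
    """Single-voxel absorbers at the given voxel indices (axial-resolution probe)."""
    absorption = np.zeros(shape, dtype=np.float32)
    for p in positions:
        absorption[tuple(int(i) for i in p)] = 1.0
    meta = {"generator": "point_target", "positions": [list(p) for p in positions]}
    return Phantom(absorption, tuple(voxel_size), meta=meta)
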