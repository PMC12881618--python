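"""End-to-end orchestration: stage graph, seeding, manifests, logging."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import klm as klm_mod
from . import phantoms as ph
from .acquisition import AcquisitionSettings, acquire
from .config import RunConfig, save_config
from .quantify import timeseries_quantify, vessel_mask, vessel_metrics
from .reconstruction import depth_encode, grid_assign, map_projection
from .scanner import simulate_trajectory
from .triggers import density_map, fill_factor, visited_mask

__all__ = ["STAGES", "run_pipeline", "stage_seed"]

log = logging.getLogger("spiralpam")

#: Pipeline stages in dependency order.
STAGES = ("scan", "schedule", "density", "klm", "phantom", "acquire", "recon", "quantify")

_DEPS = {
    "scan": (),
    "schedule": (),
    "density": ("scan", "schedule"),
    "klm": (),
    "phantom": (),
    "acquire": ("scan", "schedule", "klm", "phantom"),
    "recon": ("acquire",),
    "quantify": ("recon",),
}

_STAGE_IDS = {name: i + 1 for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31.

    A SeedSequence keyed by (global seed, stage id) fans the single run seed
    out so stage-level reruns match full-pipeline runs.
    """
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _resolve_stages(requested) -> list:
    wanted = set(requested)
    for name in requested:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    # pull in dependencies transitively
    changed = True
    while changed:
        changed = False
        for name in list(wanted):
            for dep in _DEPS[name]:
                if dep not in wanted:
                    wanted.add(dep)
                    changed = True
    return [s for s in STAGES if s in wanted]


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages (plus dependencies) and return a manifest.

    Every run writes a resolved copy of the configuration and a log file next
    to its outputs; the manifest maps stage names to output paths and summary
    metrics.  Deterministic for a fixed global seed.
    """
    requested = list(stages)
    if not requested:
        return {"stages": [], "outputs": {}, "metrics": {}}
    order = _resolve_stages(requested)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "resolved_config.yaml")
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"stages": order, "outputs": {}, "metrics": {}}
    artifacts: dict = {}
    try:
        for name in order:
            t0 = time.perf_counter()
            _run_stage(name, config, artifacts, out_dir, manifest)
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stage(name, config: RunConfig, art: dict, out_dir: Path, manifest: dict) -> None:
    if name == "scan":
        proto = config.scan_protocol()
        sample_rate = config.scanner.get("sample_rate", 500e3)
        model = config.scanner.get("model", "kinematic")
        art["trajectory"] = simulate_trajectory(
            proto, config.cantilever(), sample_rate=sample_rate, model=model
        )
        art["protocol"] = proto
        path = out_dir / "trajectory.csv"
        art["trajectory"].to_csv(path)
        manifest["outputs"]["scan"] = str(path)
        manifest["metrics"]["scan"] = {
            "cycle_duration_s": proto.cycle_duration,
            "samples": len(art["trajectory"].times),
        }
    elif name == "schedule":
        art["schedule"] = config.prf_schedule()
        manifest["metrics"]["schedule"] = {
            "n_steps": len(art["schedule"].steps),
            "span_s": list(art["schedule"].span),
        }
    elif name == "density":
        grid = config.reconstruction.get("grid_size", 512)
        fov = config.reconstruction.get("fov_diameter", 2.6e-3)
        dmap = density_map(art["trajectory"], art["schedule"], grid, fov)
        vis = visited_mask(art["trajectory"], art["schedule"], grid, fov)
        art["density"] = dmap
        path = out_dir / "density_map.tiff"
        dmap.to_tiff(path)
        dmap.summary_csv(out_dir / "density_summary.csv")
        s = dmap.summary()
        s["fill_factor_visited"] = fill_factor(dmap, vis)
        s["visited_min"] = int(dmap.grid[vis].min()) if vis.any() else 0
        s["visited_max"] = int(dmap.grid[vis].max()) if vis.any() else 0
        manifest["outputs"]["density"] = str(path)
        manifest["metrics"]["density"] = s
    elif name == "klm":
        mats = config.transducer_materials()
        stack = klm_mod.tut_design_stack(
            mats, backing_semi_infinite=config.transducer.get("backing_semi_infinite", True)
        )
        grid = klm_mod.default_frequency_grid(
            n=config.transducer.get("n_freq", 4096),
            f_max=config.transducer.get("f_max", 150e6),
        )
        resp = klm_mod.klm_two_way_response(
            stack, grid, source_impedance=config.transducer.get("source_impedance", 50.0)
        )
        metrics = klm_mod.extract_band_metrics(resp.frequencies, np.abs(resp.two_way))
        art["klm_response"] = resp
        art["band_metrics"] = metrics
        resp.spectrum_csv(out_dir / "klm_spectrum.csv")
        resp.waveform_csv(out_dir / "klm_waveform.csv")
        metrics.to_json(out_dir / "band_metrics.json")
        manifest["outputs"]["klm"] = str(out_dir / "band_metrics.json")
        manifest["metrics"]["klm"] = {
            "center_frequency_mhz": metrics.center_frequency / 1e6,
            "fractional_bandwidth_pct": metrics.fractional_bandwidth * 100.0,
        }
    elif name == "phantom":
        art["phantom"] = _build_phantom(config)
        path = out_dir / "phantom.tiff"
        art["phantom"].save(path)
        manifest["outputs"]["phantom"] = str(path)
        manifest["metrics"]["phantom"] = {
            "shape": list(art["phantom"].shape),
            "occupied_fraction": float((art["phantom"].absorption > 0).mean()),
        }
    elif name == "acquire":
        acq = dict(config.acquisition)
        settings = AcquisitionSettings(seed=stage_seed(config.seed, "acquire"), **acq)
        impulse = _acquisition_impulse(art, settings)
        samples = acquire(art["trajectory"], art["schedule"], art["phantom"], impulse, settings)
        art["samples"] = samples
        prefix = out_dir / "samples"
        samples.save(prefix)
        manifest["outputs"]["acquire"] = str(prefix) + "_ascans.npy"
        manifest["metrics"]["acquire"] = {"n_shots": len(samples)}
    elif name == "recon":
        grid = config.reconstruction.get("grid_size", 512)
        fov = config.reconstruction.get("fov_diameter", 2.6e-3)
        vol = grid_assign(
            art["samples"],
            grid,
            fov,
            k_neighbors=config.reconstruction.get("k_neighbors", 4),
            power=config.reconstruction.get("power", 1.0),
        )
        art["volume"] = vol
        art["map"] = map_projection(vol)
        art["depth"] = depth_encode(vol)
        vol.save(out_dir / "volume.tiff")
        art["map"].to_tiff(out_dir / "map.tiff")
        art["depth"].to_tiff(out_dir / "depth.tiff")
        manifest["outputs"]["recon"] = str(out_dir / "map.tiff")
        manifest["metrics"]["recon"] = {
            "grid_size": grid,
            "filled_pixels": int(vol.fill_mask.sum()),
        }
    elif name == "quantify":
        q = config.quantification
        mimg = art["map"]
        mask = vessel_mask(mimg, q.get("mask_method", "otsu"), q.get("fixed_threshold"))
        metrics = vessel_metrics(mask, mimg.pixel_size)
        art["vessel_metrics"] = metrics
        with open(out_dir / "vessel_metrics.json", "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2)
        manifest["outputs"]["quantify"] = str(out_dir / "vessel_metrics.json")
        manifest["metrics"]["quantify"] = metrics.to_dict()
    else:  # pragma: no cover
        raise ValueError(f"missing upstream artifact for stage {name!r}")


def _build_phantom(config: RunConfig):
    p = config.phantom
    kind = p.get("kind", "vessel")
    fov = config.reconstruction.get("fov_diameter", 2.6e-3)
    if kind == "vessel":
        params = dict(p.get("params", {}))
        params.setdefault("seed", stage_seed(config.seed, "phantom"))
        shape = tuple(p.get("shape", (96, 96, 32)))
        voxel = tuple(p.get("voxel_size", (fov / (shape[0] - 1),) * 2 + (10e-6,)))
        phantom = ph.make_vessel_phantom(ph.VesselTreeParams(**params), shape, voxel)
    elif kind == "edge":
        shape = tuple(p.get("shape", (128, 128, 16)))
        voxel = tuple(p.get("voxel_size", (5e-6, 5e-6, 10e-6)))
        phantom = ph.make_edge_target(shape, voxel, p.get("edge_axis", 0), p.get("depth", 50e-6))
    elif kind == "grid":
        shape = tuple(p.get("shape", (128, 128, 16)))
        voxel = tuple(p.get("voxel_size", (5e-6, 5e-6, 10e-6)))
        phantom = ph.make_grid_target(
            shape, voxel, p.get("pitch", 100e-6), p.get("bar_width", 40e-6), p.get("depth", 50e-6)
        )
    elif kind == "point":
        shape = tuple(p.get("shape", (64, 64, 64)))
        voxel = tuple(p.get("voxel_size", (5e-6, 5e-6, 5e-6)))
        phantom = ph.make_point_target(shape, voxel, p.get("positions", ((32, 32, 32),)))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    # center the phantom on the scan axis
    ext_x = (phantom.shape[0] - 1) * phantom.voxel_size[0]
    ext_y = (phantom.shape[1] - 1) * phantom.voxel_size[1]
    phantom.origin = (-ext_x / 2.0, -ext_y / 2.0, phantom.origin[2])
    return phantom


def _acquisition_impulse(art: dict, settings: AcquisitionSettings) -> np.ndarray:
    """Transducer two-way waveform resampled to the digitizer rate."""
    resp = art.get("klm_response")
    if resp is None:
        return np.array([1.0])
    t_src = np.arange(len(resp.waveform)) * resp.dt
    # keep the leading pulse (zero-phase reference at the origin)
    n_keep = min(len(resp.waveform), int(0.5e-6 / resp.dt))
    t_new = np.arange(0, t_src[n_keep - 1], 1.0 / settings.sampling_rate)
    imp = np.interp(t_new, t_src[:n_keep], resp.waveform[:n_keep])
    peak = np.abs(imp).max()
    return imp / peak if peak > 0 else np.array([1.0])
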