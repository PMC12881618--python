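"""Structured run configuration (YAML-compatible) with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .materials import MATERIALS, MaterialSpec
from .scanner import CantileverSpec, ScanProtocol
from .triggers import PrfSchedule, reference_schedule

__all__ = ["RunConfig", "load_config", "save_config"]

_KNOWN_SECTIONS = {
    "seed",
    "output_dir",
    "scanner",
    "schedule",
    "transducer",
    "phantom",
    "acquisition",
    "reconstruction",
    "quantification",
}


def _check_keys(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Nested configuration for the full pipeline.

    Sections not present fall back to the package defaults (the handheld
    probe's protocol, the reference PRF schedule, the design transducer
    stack, a seeded vessel phantom, and 250 MHz acquisition settings).
    """

    seed: int = 0
    output_dir: str = "runs/run"
    scanner: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    transducer: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    reconstruction: dict = field(default_factory=dict)
    quantification: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys(
            self.scanner, {"protocol", "cantilever", "sample_rate", "model"}, "scanner"
        )
        _check_keys(self.schedule, {"steps", "prf_scale"}, "schedule")
        _check_keys(
            self.transducer,
            {"materials", "f_max", "n_freq", "source_impedance", "backing_semi_infinite"},
            "transducer",
        )
        _check_keys(
            self.phantom,
            {"kind", "shape", "voxel_size", "params", "pitch", "bar_width", "depth", "edge_axis", "positions"},
            "phantom",
        )
        _check_keys(
            self.acquisition,
            {"sampling_rate", "speed_of_sound", "record_length", "focal_spot_sigma", "noise_sigma"},
            "acquisition",
        )
        _check_keys(
            self.reconstruction,
            {"grid_size", "fov_diameter", "k_neighbors", "power"},
            "reconstruction",
        )
        _check_keys(
            self.quantification,
            {"mask_method", "fixed_threshold", "split_threshold"},
            "quantification",
        )

    # ---- resolved objects -------------------------------------------------
    def scan_protocol(self) -> ScanProtocol:
        return ScanProtocol(**self.scanner.get("protocol", {}))

    def cantilever(self) -> CantileverSpec:
        return CantileverSpec(**self.scanner.get("cantilever", {}))

    def prf_schedule(self) -> PrfSchedule:
        if "steps" in self.schedule:
            sched = PrfSchedule.from_dict({"steps": self.schedule["steps"]})
        else:
            sched = reference_schedule()
        scale = self.schedule.get("prf_scale", 1.0)
        return sched.scaled_prf(scale) if scale != 1.0 else sched

    def transducer_materials(self) -> dict[str, MaterialSpec]:
        mats = dict(MATERIALS)
        for name, over in self.transducer.get("materials", {}).items():
            base = mats.get(name)
            d = base.to_dict() if base else {"name": name}
            d.update(over)
            d["name"] = name
            mats[name] = MaterialSpec.from_dict(d)
        return mats

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "scanner": self.scanner,
            "schedule": self.schedule,
            "transducer": self.transducer,
            "phantom": self.phantom,
            "acquisition": self.acquisition,
            "reconstruction": self.reconstruction,
            "quantification": self.quantification,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, _KNOWN_SECTIONS, "top level")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
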