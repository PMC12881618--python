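"""Acoustic material constants for the layered transparent-transducer model.

The device publication prints layer thicknesses but no material constants, so
this table ships literature-class defaults; every value is overridable in
config.  The silica-epoxy 0-3 composite is pinned near the DeSilets two-layer
matching rule ``Z1 = (Zp^4 Zw^3)^(1/7) ≈ 8.9 MRayl`` for LNO into water, which
is also quarter-wave-consistent with the printed 30 um first matching layer at
the design center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MaterialSpec", "MATERIALS", "get_material"]


@dataclass(frozen=True)
class MaterialSpec:
    """Homogeneous acoustic material, optionally piezoelectric.

    ``attenuation_db_mhz_cm`` is a linear-in-frequency loss hook
    (dB per MHz per cm), zero by default.
    """

    name: str
    longitudinal_velocity: float  # m/s
    density: float  # kg/m^3
    kt: float | None = None  # thickness-mode coupling (piezo only)
    clamped_permittivity: float | None = None  # relative, clamped (piezo only)
    attenuation_db_mhz_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.longitudinal_velocity <= 0 or self.density <= 0:
            raise ValueError("velocity and density must be > 0")
        if self.kt is not None and not 0.0 < self.kt < 1.0:
            raise ValueError("kt must lie in (0, 1)")
        if self.attenuation_db_mhz_cm < 0:
            raise ValueError("attenuation must be >= 0")

    @property
    def acoustic_impedance(self) -> float:
        """Characteristic impedance rho * v, Rayl."""
        return self.longitudinal_velocity * self.density

    @property
    def is_piezo(self) -> bool:
        return self.kt is not None and self.clamped_permittivity is not None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "longitudinal_velocity": self.longitudinal_velocity,
            "density": self.density,
            "kt": self.kt,
            "clamped_permittivity": self.clamped_permittivity,
            "attenuation_db_mhz_cm": self.attenuation_db_mhz_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSpec":
        return cls(**d)


MATERIALS: dict[str, MaterialSpec] = {
    # 36-deg rotated Y-cut lithium niobate, thickness mode
    "lno_36y": MaterialSpec("lno_36y", 7340.0, 4640.0, kt=0.49, clamped_permittivity=39.0),
    # silica-loaded 0-3 epoxy composite first matching layer
    "silica_epoxy_composite": MaterialSpec("silica_epoxy_composite", 4200.0, 2100.0),
    # EPO-TEK 301-class optical epoxy (second matching and backing)
    "epoxy": MaterialSpec("epoxy", 2650.0, 1150.0),
    "water": MaterialSpec("water", 1480.0, 1000.0),
    "air": MaterialSpec("air", 343.0, 1.2),
}


def get_material(name: str) -> MaterialSpec:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIALS)}"
        ) from None
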