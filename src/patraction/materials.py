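"""Tissue elastic properties and plane-strain constitutive operators.

All tissues are isotropic linear elastic. The default table reproduces the
property set used for full-scale MRI-derived simulations of the same traction
device (moduli in MPa, densities in kg/m^3); the cerebrospinal fluid is
specified through its bulk modulus K with the Young modulus derived from the
standard identity E = 3K(1 - 2*nu).

Units follow the consistent mm-MPa-N system used throughout the package.
Densities are carried for completeness; the quasi-static solver does not use
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import (
    CORD, CSF, DISC_LEVELS, EPIDURAL_FAT, MAT, MUSCLE, RegionLabel, SKIN,
    SOFT_TISSUE, SUBCUT_FAT, VERTEBRA_LEVELS, DISC, VERTEBRA,
)

__all__ = [
    "Material", "MaterialTable", "SafetyThresholds",
    "csf_effective_modulus", "plane_strain_matrix", "default_table",
]


def csf_effective_modulus(bulk_modulus_K: float, nu: float) -> float:
    """Young modulus of a near-incompressible fluid-like solid, E = 3K(1-2nu).

    Raises for nu >= 0.5 (the incompressible limit has no finite E).
    """
    if not 0.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {nu}")
    if bulk_modulus_K <= 0.0:
        raise ValueError(f"bulk modulus must be positive, got {bulk_modulus_K}")
    return 3.0 * bulk_modulus_K * (1.0 - 2.0 * nu)


def plane_strain_matrix(E: float, nu: float) -> np.ndarray:
    """3x3 plane-strain operator mapping (exx, eyy, gxy) -> (sxx, syy, txy)."""
    if not 0.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {nu}")
    if E <= 0.0:
        raise ValueError(f"Young modulus must be positive, got {E}")
    c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array([
        [1.0 - nu, nu, 0.0],
        [nu, 1.0 - nu, 0.0],
        [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
    ])


@dataclass(frozen=True)
class Material:
    """Isotropic linear elastic constants: E (MPa), nu (-), rho (kg/m^3)."""

    E: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if self.E <= 0.0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"nu must lie in (0, 0.5), got {self.nu}")
        if self.rho <= 0.0:
            raise ValueError(f"rho must be positive, got {self.rho}")


# Bulk modulus (MPa) and Poisson ratio defining the CSF entry.
CSF_BULK_MODULUS_MPA = 2250.0
CSF_POISSON = 0.499


def _default_entries() -> dict[RegionLabel, Material]:
    entries: dict[RegionLabel, Material] = {
        SKIN: Material(160.0, 0.49, 1020.0),
        MUSCLE: Material(7.0, 0.49, 1100.0),
        SOFT_TISSUE: Material(23.5, 0.49, 1057.0),
        SUBCUT_FAT: Material(3.0, 0.49, 920.0),
        EPIDURAL_FAT: Material(3.0, 0.49, 920.0),
        CSF: Material(csf_effective_modulus(CSF_BULK_MODULUS_MPA, CSF_POISSON),
                      CSF_POISSON, 1000.0),
        CORD: Material(10.0, 0.49, 1057.0),
        # Bed-mat layer: not part of the tissue inventory; foam-like pad.
        MAT: Material(5.0, 0.30, 100.0),
    }
    vert = Material(17000.0, 0.30, 1800.0)
    disc = Material(17.0, 0.49, 1100.0)
    for lv in VERTEBRA_LEVELS:
        entries[VERTEBRA(lv)] = vert
    for lv in DISC_LEVELS:
        entries[DISC(lv)] = disc
    return entries


@dataclass
class MaterialTable:
    """Per-region material table with config round-tripping.

    ``nu_cap`` truncates Poisson ratios when building constitutive operators
    (default 0.495): nu = 0.499 for the CSF strip conditions the stiffness
    matrix poorly at this geometry scale while leaving the disc-ROI response
    unchanged. Lookups still report the stored (uncapped) values.
    """

    entries: dict[RegionLabel, Material] = field(default_factory=_default_entries)
    nu_cap: float = 0.495

    def lookup(self, region: RegionLabel) -> Material:
        try:
            return self.entries[region]
        except KeyError:
            raise KeyError(f"no material entry for region {region}") from None

    def lookup_by_id(self, region_id: int) -> Material:
        from .regions import ID_TO_LABEL
        return self.lookup(ID_TO_LABEL[region_id])

    def operator(self, region: RegionLabel) -> np.ndarray:
        """Plane-strain constitutive matrix, with the nu cap applied."""
        m = self.lookup(region)
        return plane_strain_matrix(m.E, min(m.nu, self.nu_cap))

    def capped_nu(self, region: RegionLabel) -> float:
        return min(self.lookup(region).nu, self.nu_cap)

    # -- config round-trip -------------------------------------------------
    def to_config(self) -> dict[str, dict[str, float]]:
        return {str(lab): {"E": m.E, "nu": m.nu, "rho": m.rho}
                for lab, m in self.entries.items()}

    @classmethod
    def from_config(cls, block: dict[str, dict[str, float]] | None,
                    nu_cap: float = 0.495) -> "MaterialTable":
        """Build the default table, then apply per-region overrides."""
        table = cls(nu_cap=nu_cap)
        if not block:
            return table
        by_name = {str(lab): lab for lab in table.entries}
        for name, props in block.items():
            if name not in by_name:
                raise KeyError(f"unknown region {name!r} in material block; "
                               f"valid regions: {sorted(by_name)}")
            lab = by_name[name]
            base = table.entries[lab]
            table.entries[lab] = Material(
                E=float(props.get("E", base.E)),
                nu=float(props.get("nu", base.nu)),
                rho=float(props.get("rho", base.rho)),
            )
        return table


def default_table() -> MaterialTable:
    return MaterialTable()


@dataclass(frozen=True)
class SafetyThresholds:
    """Published damage thresholds for intervertebral disc tissue."""

    ultimate_stress_MPa: float = 2.94
    ultimate_stress_sd: float = 1.05
    ultimate_strain_pct: float = 21.3
    ultimate_strain_sd: float = 2.1

    def __post_init__(self) -> None:
        for name in ("ultimate_stress_MPa", "ultimate_stress_sd",
                     "ultimate_strain_pct", "ultimate_strain_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
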