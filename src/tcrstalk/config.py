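"""Shared configuration: geometric criteria, van der Waals radii, physical constants.

All distance thresholds are in angstroms and angles in degrees. The hydrogen-bond
criterion is a heavy-atom one (donor-acceptor distance window plus a minimum
donor-antecedent-donor-acceptor angle); crystal structures analysed here carry no
hydrogens, so explicit H positions are never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

# Bondi van der Waals radii (angstrom) for the heavy elements that occur in
# protein ATOM records.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Atomic masses in amu, used for mass-weighted covariance analysis.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

# Physical constants (SI) and unit-bridging factors.
BOLTZMANN_J_PER_K = 1.380649e-23
HBAR_J_S = 1.054571817e-34
ATOMIC_MASS_KG = 1.66053906660e-27
GAS_CONSTANT_CAL = 1.98720425864083  # cal mol^-1 K^-1

# Ideal serine internal coordinates used for side-chain construction.
IDEAL_CA_CB = 1.53  # angstrom
IDEAL_CB_OG = 1.42  # angstrom
IDEAL_TETRAHEDRAL_ANGLE = 110.5  # degrees


@dataclass(frozen=True)
class GeometryConfig:
    """Tunable thresholds for hydrogen bonds, clashes and the cavity probe.

    Attributes
    ----------
    hb_min, hb_max : float
        Donor-acceptor heavy-atom distance window for a hydrogen bond (A).
    hb_angle_min : float
        Minimum donor-antecedent - donor - acceptor angle (degrees).
    vdw_radii : dict
        Per-element van der Waals radii (A); elements absent from the table
        fall back to the carbon radius.
    clash_tolerance : float
        Allowed interpenetration before a pair counts as a steric clash (A).
    probe_radius : float
        Radius of the spherical probe used to decide whether a cavity is
        present (A); the default is water-sized.
    """

    hb_min: float = 2.4
    hb_max: float = 3.5
    hb_angle_min: float = 90.0
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    clash_tolerance: float = 0.4
    probe_radius: float = 1.4

    def vdw(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), self.vdw_radii["C"])

    def with_overrides(self, **kwargs) -> "GeometryConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometryConfig":
        """Load overrides from a small YAML/key-value file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
        if "vdw_radii" in data:
            merged = dict(DEFAULT_VDW_RADII)
            merged.update({k.upper(): float(v) for k, v in data["vdw_radii"].items()})
            data["vdw_radii"] = merged
        return cls(**data)
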