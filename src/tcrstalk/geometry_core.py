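"""Elementary structural geometry.

Distances, least-squares rigid-body superposition (Kabsch, via scipy's
rotation estimator), heavy-atom hydrogen-bond detection, van der Waals clash
detection, and a spherical cavity probe. These are the primitives behind the
stalk-distance survey, the G107S placement scoring, and trajectory RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import GeometryConfig
from .structure_model import AtomRecord, BACKBONE_NAMES, ResidueRecord


class GeometryError(Exception):
    pass


class DegenerateInputError(GeometryError):
    pass


def distance(p, q) -> float:
    """Euclidean distance between two 3-vectors (angstrom)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise GeometryError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def angle_deg(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class Superposition:
    rotation: np.ndarray      # (3,3), proper (det +1)
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid-body superposition of paired coordinate sets.

    Returns the proper rotation R and translation t minimizing
    ``|| R·mobile + t - reference ||`` together with the post-fit RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError("paired (n,3) coordinate sets required")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateInputError("superposition needs at least 3 points")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mob - mob_mean
    ref_c = ref - ref_mean
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("mobile points are (near-)collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref_mean - R @ mob_mean
    return Superposition(rotation=R, translation=t, rmsd=float(rssd) / np.sqrt(n))


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD of paired coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarAtom:
    """An N/O heavy atom that may donate/accept, with its covalent antecedent."""
    atom: AtomRecord
    antecedent: np.ndarray | None   # coordinate of bonded heavy atom, if known
    label: str                      # e.g. "B/ASP108/O"
    is_backbone: bool


@dataclass
class HBond:
    donor: PolarAtom
    acceptor: PolarAtom
    da_distance: float
    classification: tuple[str, str]  # ("backbone"|"side-chain") per partner

    @property
    def labels(self) -> tuple[str, str]:
        return (self.donor.label, self.acceptor.label)


def polar_atoms_of(residues, chain_id: str = "?") -> list[PolarAtom]:
    """Collect N/O atoms of residues with a nearest-in-residue antecedent."""
    out: list[PolarAtom] = []
    for res in residues:
        for atom in res.atoms:
            if atom.element not in ("N", "O"):
                continue
            others = [a for a in res.atoms if a is not atom]
            ante = None
            if others:
                ante = min(others, key=lambda a: np.linalg.norm(a.coord - atom.coord)).coord
            out.append(PolarAtom(
                atom=atom,
                antecedent=ante,
                label=f"{chain_id}/{res.label}/{atom.name}",
                is_backbone=atom.name in BACKBONE_NAMES,
            ))
    return out


def _angle_ok(donor: PolarAtom, acceptor: PolarAtom, min_deg: float) -> bool:
    if donor.antecedent is None:
        return True
    return angle_deg(donor.antecedent, donor.atom.coord, acceptor.atom.coord) >= min_deg


def detect_hbonds(polar_atoms: list[PolarAtom],
                  config: GeometryConfig | None = None,
                  involving: set[int] | None = None) -> list[HBond]:
    """All donor-acceptor N/O pairs satisfying the distance+angle criterion.

    Hydrogens are not modeled, so every N/O is treated as both potential donor
    and acceptor; a pair is reported once, oriented by whichever partner
    satisfies the antecedent-angle criterion. ``involving``, when given,
    restricts output to bonds touching atoms whose ``id()`` is in the set
    (used to score a newly placed side chain against its environment).
    Results are deduplicated and sorted by distance.
    """
    cfg = config or GeometryConfig()
    bonds: list[HBond] = []
    n = len(polar_atoms)
    coords = np.array([p.atom.coord for p in polar_atoms])
    for i in range(n):
        for j in range(i + 1, n):
            if involving is not None and (
                id(polar_atoms[i].atom) not in involving
                and id(polar_atoms[j].atom) not in involving
            ):
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if not (cfg.hb_min <= d <= cfg.hb_max):
                continue
            pi, pj = polar_atoms[i], polar_atoms[j]
            if _angle_ok(pi, pj, cfg.hb_angle_min):
                donor, acceptor = pi, pj
            elif _angle_ok(pj, pi, cfg.hb_angle_min):
                donor, acceptor = pj, pi
            else:
                continue
            kind = tuple("backbone" if p.is_backbone else "side-chain"
                         for p in (donor, acceptor))
            bonds.append(HBond(donor, acceptor, d, kind))
    bonds.sort(key=lambda b: b.da_distance)
    return bonds


# ---------------------------------------------------------------------------
# steric clashes
# ---------------------------------------------------------------------------

@dataclass
class ClashReport:
    pairs: list[tuple[AtomRecord, AtomRecord, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.pairs)

    @property
    def max_overlap(self) -> float:
        return max((p[2] for p in self.pairs), default=0.0)


def detect_clashes(placed_atoms: list[AtomRecord],
                   environment_atoms: list[AtomRecord],
                   config: GeometryConfig | None = None) -> ClashReport:
    """Van der Waals overlaps between placed atoms and their environment.

    A pair clashes when ``d < r_vdw(i) + r_vdw(j) - tolerance``; the listed
    overlap is ``r_vdw(i)+r_vdw(j)-d-tolerance``. Bonded (1-2/1-3) neighbors
    must be excluded by the caller from ``environment_atoms`` — the function
    itself has no bond topology.
    """
    cfg = config or GeometryConfig()
    report = ClashReport()
    if not placed_atoms or not environment_atoms:
        return report
    env_coords = np.array([a.coord for a in environment_atoms])
    env_radii = np.array([cfg.vdw(a.element) for a in environment_atoms])
    for atom in placed_atoms:
        d = np.linalg.norm(env_coords - atom.coord, axis=1)
        overlap = cfg.vdw(atom.element) + env_radii - d - cfg.clash_tolerance
        for k in np.nonzero(overlap > 0)[0]:
            report.pairs.append((atom, environment_atoms[int(k)], float(overlap[k])))
    report.pairs.sort(key=lambda p: -p[2])
    return report


# ---------------------------------------------------------------------------
# cavity probe
# ---------------------------------------------------------------------------

@dataclass
class GapProbe:
    probe_center: np.ndarray
    max_free_radius: float
    gap_present: bool


def probe_gap(center, environment_atoms: list[AtomRecord],
              config: GeometryConfig | None = None) -> GapProbe:
    """Largest sphere centered at ``center`` free of environment vdW spheres.

    ``max_free_radius = min_i (d(center, atom_i) - r_vdw(atom_i))``; the gap is
    declared present when it admits the configured probe radius.
    """
    cfg = config or GeometryConfig()
    if not environment_atoms:
        raise GeometryError("probe_gap: empty environment")
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise GeometryError("probe_gap: non-finite center")
    d = np.linalg.norm(np.array([a.coord for a in environment_atoms]) - center, axis=1)
    radii = np.array([cfg.vdw(a.element) for a in environment_atoms])
    free = float(np.min(d - radii))
    return GapProbe(probe_center=center, max_free_radius=free,
                    gap_present=free >= cfg.probe_radius)


def residue_clash_exclusion(chain_residues: list[ResidueRecord],
                            index: int) -> set[int]:
    """``id()`` set of atoms exempt from clash/probe checks for a side chain
    placed at ``chain_residues[index]``: the residue's own atoms plus the
    backbone atoms of its chain neighbors (covalently coupled within a few
    bonds of the placed Cβ/Oγ, where vdW criteria do not apply)."""
    excluded: set[int] = set()
    for a in chain_residues[index].atoms:
        excluded.add(id(a))
    for j in (index - 1, index + 1):
        if 0 <= j < len(chain_residues):
            for a in chain_residues[j].atoms:
                if a.name in BACKBONE_NAMES:
                    excluded.add(id(a))
    return excluded
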