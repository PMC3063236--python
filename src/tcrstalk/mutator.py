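"""In-silico G107S substitution on a rigid backbone.

The serine side chain is built from ideal internal coordinates (Cα-Cβ 1.53 Å,
Cβ-Oγ 1.42 Å, tetrahedral angles 110.5°) on the unchanged backbone of the
residue at IMGT 107, scanning the three staggered χ1 rotamers. Each placement
is scored by van der Waals clashes against the rest of the structure and by
the hydrogen bonds its Oγ can make; the verdict is existential — the mutation
"fits" if any rotamer is clash-free. No other atom is moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    GeometryConfig,
    IDEAL_CA_CB,
    IDEAL_CB_OG,
    IDEAL_TETRAHEDRAL_ANGLE,
)
from .geometry_core import (
    ClashReport,
    HBond,
    detect_clashes,
    detect_hbonds,
    polar_atoms_of,
    PolarAtom,
    residue_clash_exclusion,
)
from .structure_model import (
    AtomRecord,
    ImgtAnchor,
    ResidueRecord,
    StructureModel,
    StructureError,
)

DEFAULT_CHI1_SET = (-60.0, 60.0, 180.0)


class MutationError(Exception):
    pass


@dataclass
class RotamerPlacement:
    chi1: float
    cb_coord: np.ndarray
    og_coord: np.ndarray
    clash: ClashReport
    hbond_partners: list[HBond] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return self.clash.count == 0

    @property
    def n_hbonds(self) -> int:
        return len(self.hbond_partners)


@dataclass
class MutationResult:
    placements: list[RotamerPlacement]
    best: int | None

    @property
    def verdict(self) -> str:
        return "fits" if self.best is not None else "clashes"

    @property
    def best_placement(self) -> RotamerPlacement | None:
        return self.placements[self.best] if self.best is not None else None


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             bond: float = IDEAL_CA_CB,
             angle: float = IDEAL_TETRAHEDRAL_ANGLE) -> np.ndarray:
    """Ideal Cβ position for an L-amino acid from its backbone N, Cα, C.

    The Cβ sits at ``bond`` from Cα with equal N-Cα-Cβ and C-Cα-Cβ angles,
    on the side of the backbone plane dictated by L-chirality.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    u_n = n - ca
    u_c = c - ca
    nn, nc = np.linalg.norm(u_n), np.linalg.norm(u_c)
    if nn == 0 or nc == 0:
        raise MutationError("degenerate backbone: coincident atoms")
    u_n /= nn
    u_c /= nc
    cross = np.cross(u_n, u_c)
    s = np.linalg.norm(cross)
    if s < 1e-6:
        raise MutationError("degenerate backbone: collinear N, CA, C")
    bisector = -(u_n + u_c)
    bisector /= np.linalg.norm(bisector)
    perp = cross / s
    # choose in-plane/out-of-plane mixture so that angle(N-CA-CB) == angle
    target = np.cos(np.radians(angle))
    denom = float(np.dot(bisector, u_n))
    alpha = target / denom
    alpha = np.clip(alpha, -1.0, 1.0)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    direction = alpha * bisector + beta * perp
    return ca + bond * direction / np.linalg.norm(direction)


def place_dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   bond: float, angle_deg_: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D so that |C-D|=bond, angle(B,C,D)=angle, dihedral(A,B,C,D)=chi."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n_plane = np.cross(ab, bc)
    norm = np.linalg.norm(n_plane)
    if norm < 1e-9:
        raise MutationError("degenerate frame for dihedral placement")
    n_plane /= norm
    m = np.cross(n_plane, bc)
    ang = np.radians(angle_deg_)
    dih = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n_plane


def serine_og(n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
              chi1: float) -> np.ndarray:
    """Oγ position for a given χ1 (dihedral N-Cα-Cβ-Oγ)."""
    return place_dihedral(n, ca, cb, IDEAL_CB_OG, IDEAL_TETRAHEDRAL_ANGLE, chi1)


def _environment(struct: StructureModel, anchor: ImgtAnchor,
                 model: int = 0) -> tuple[list[AtomRecord], list[ResidueRecord]]:
    """All heavy atoms eligible for clash checks against the placed side chain,
    plus the residue list used for hydrogen-bond candidates."""
    chain = struct.get_chain(anchor.beta_chain_id, model=model)
    idx = chain.residues.index(anchor.pos107)
    excluded = residue_clash_exclusion(chain.residues, idx)
    env: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    for ch in struct.models[model]:
        for res in ch.residues:
            if res is not anchor.pos107:
                residues.append(res)
            for atom in res.atoms:
                if atom.element == "H" or id(atom) in excluded:
                    continue
                env.append(atom)
    return env, residues


def place_serine(struct: StructureModel, anchor: ImgtAnchor,
                 chi1_set=DEFAULT_CHI1_SET,
                 config: GeometryConfig | None = None,
                 model: int = 0) -> MutationResult:
    """Scan χ1 rotamers of a serine at position 107 and score each placement.

    The residue at 107 must be G (the substitution target) or S (in which case
    the scan doubles as a self-consistency check against the deposited side
    chain). Ranking among feasible placements: most hydrogen bonds, then least
    steric strain, then proximity to the gauche- rotamer (χ1 = -60°).
    """
    cfg = config or GeometryConfig()
    res107 = anchor.pos107
    if res107.aa not in ("G", "S"):
        raise MutationError(
            f"unsupported mutation target {res107.label}: residue must be G or S"
        )
    if not chi1_set:
        raise MutationError("chi1_set must be non-empty")
    n = res107.require_atom("N").coord
    ca = res107.require_atom("CA").coord
    c = res107.require_atom("C").coord
    cb = build_cb(n, ca, c)
    env_atoms, env_residues = _environment(struct, anchor, model=model)
    env_polar = polar_atoms_of(env_residues, chain_id=anchor.beta_chain_id)

    placements: list[RotamerPlacement] = []
    for chi1 in chi1_set:
        og = serine_og(n, ca, cb, chi1)
        cb_atom = AtomRecord(name="CB", element="C", coord=cb)
        og_atom = AtomRecord(name="OG", element="O", coord=og)
        clash = detect_clashes([cb_atom, og_atom], env_atoms, cfg)
        og_polar = PolarAtom(atom=og_atom, antecedent=cb,
                             label=f"{anchor.beta_chain_id}/SER{res107.number}/OG",
                             is_backbone=False)
        hbonds = detect_hbonds(env_polar + [og_polar], cfg,
                               involving={id(og_atom)})
        placements.append(RotamerPlacement(
            chi1=float(chi1), cb_coord=cb, og_coord=og,
            clash=clash, hbond_partners=hbonds,
        ))

    feasible = [i for i, p in enumerate(placements) if p.feasible]
    best = None
    if feasible:
        best = min(feasible, key=lambda i: (
            -placements[i].n_hbonds,
            placements[i].clash.max_overlap,
            abs(placements[i].chi1 + 60.0),
        ))
    return MutationResult(placements=placements, best=best)


def apply_placement(struct: StructureModel, anchor: ImgtAnchor,
                    placement: RotamerPlacement, model: int = 0) -> StructureModel:
    """Return a copy of the structure with SER built at position 107.

    Every pre-existing atom keeps its exact coordinates; only CB and OG are
    added (replacing any prior CB/OG of a serine target).
    """
    new_models = []
    for imodel, chains in enumerate(struct.models):
        new_chains = []
        for ch in chains:
            new_residues = []
            for res in ch.residues:
                atoms = [AtomRecord(a.name, a.element, a.coord.copy(), a.serial)
                         for a in res.atoms]
                if imodel == model and res is anchor.pos107:
                    atoms = [a for a in atoms if a.name not in ("CB", "OG")]
                    atoms.append(AtomRecord("CB", "C", placement.cb_coord.copy()))
                    atoms.append(AtomRecord("OG", "O", placement.og_coord.copy()))
                    new_residues.append(ResidueRecord(
                        aa="S", number=res.number, icode=res.icode,
                        name3="SER", atoms=atoms))
                else:
                    new_residues.append(ResidueRecord(
                        aa=res.aa, number=res.number, icode=res.icode,
                        name3=res.name3, atoms=atoms))
            new_chains.append(type(ch)(ch.chain_id, new_residues))
        new_models.append(new_chains)
    return StructureModel(pdb_id=struct.pdb_id, models=new_models)
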