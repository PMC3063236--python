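"""Synthetic fixtures: hairpin loop structures, Gaussian trajectories, toy FASTA.

Everything here is a geometric or statistical stand-in, generated as a pure
function of (spec, seed):

* :func:`make_hairpin` builds an idealized beta-hairpin CDR3-like loop — two
  antiparallel strands joined by a turn — with the stalk residue (IMGT 107)
  carrying either a glycine (leaving an empty pocket above the backbone plane)
  or a serine built from ideal internal coordinates. An optional framework
  tyrosine strand supplies the Y40 hydroxyl and the IMGT-42 Cα. Target values
  for the stalk distance triple (a, b, c) can be requested, which lets the
  generator emit stand-ins for published per-structure distances when the
  deposited coordinate files themselves are not available.
* :func:`make_gaussian_trajectory` samples frames from a Gaussian ensemble
  with a known mass-weighted mode spectrum orthogonal to the rigid-body
  subspace, returning the closed-form quasi-harmonic entropy as an oracle.
* :func:`make_trbv_fasta` writes V-gene C-terminus FASTA sets with exact
  requested CASS/CASG/other compositions.

Hairpin fixtures are stand-ins, not physical loop models: local backbone
geometry is idealized and side chains beyond the stalk Cβ/Oγ and the Y40
hydroxyl arm are schematic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry_core import distance
from .mutator import build_cb, serine_og
from .sequence_survey import AA_ALPHABET
from .structure_model import (
    AtomRecord,
    ChainModel,
    ONE_TO_THREE,
    ResidueRecord,
    StructureModel,
    write_pdb,
)
from .trajectory_analysis import TrajectoryEnsemble, analytic_entropy

_ELEMENT_OF_NAME = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
                    "OG": "O", "CG": "C", "CZ": "C", "OH": "O"}

# strand geometry (angstrom)
STRAND1_SPACING = 3.5      # Cα-Cα step of the stalk-bearing strand
STRAND2_SPACING = 3.8      # Cα-Cα step of the countercurrent strand
TURN_MARGIN = 4.5          # x-offset of the turn arc beyond strand 1
STRAND1_TILT_DEG = 50.0    # roll of the stalk strand plane about its axis, so
                           # the 107 side chain leaves the loop plane
CA_OG_GAP = 2.43           # |Cα-Oγ| implied by ideal serine internal coords


class FixtureError(Exception):
    pass


@dataclass(frozen=True)
class HairpinSpec:
    """Specification of one synthetic hairpin loop.

    ``loop_sequence`` must start with C and have ≥ 8 residues; the stalk
    (G or S site) is its 4th residue. ``dist_a/b/c`` are optional target
    values for the stalk distance triple; ``dist_b`` requires
    ``include_y40``. ``occlude_stalk`` plants blocker atoms at every χ1
    rotamer Oγ site so that no serine placement can fit.
    """

    loop_sequence: str
    stalk_index: int = 3
    include_y40: bool = True
    strand_separation: float = 4.8
    dist_a: float | None = None
    dist_b: float | None = None
    dist_c: float | None = 4.9
    serine_chi1: float | None = None   # None: use the reference rotamer
    occlude_stalk: bool = False
    name: str = "hairpin"
    chain_id: str = "B"

    def __post_init__(self):
        if len(self.loop_sequence) < 8:
            raise FixtureError("loop sequence must have at least 8 residues")
        if not set(self.loop_sequence) <= AA_ALPHABET:
            raise FixtureError("loop sequence must use the 20 standard residues")
        if self.loop_sequence[0] != "C":
            raise FixtureError("loop sequence must start with the conserved C104")
        if self.dist_b is not None and not self.include_y40:
            raise FixtureError("dist_b target requires include_y40")


def _residue(aa: str, number: int, atom_specs: list[tuple[str, np.ndarray]]) -> ResidueRecord:
    atoms = [AtomRecord(name=nm, element=_ELEMENT_OF_NAME[nm], coord=np.asarray(xyz, float))
             for nm, xyz in atom_specs]
    return ResidueRecord(aa=aa, number=number, name3=ONE_TO_THREE.get(aa, "UNK"),
                         atoms=atoms)


def _roll_x(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    y, z = v[1], v[2]
    return np.array([v[0], y * np.cos(th) - z * np.sin(th),
                     y * np.sin(th) + z * np.cos(th)])


def _strand1_residue(aa: str, number: int, ordinal: int) -> ResidueRecord:
    ca = np.array([ordinal * STRAND1_SPACING, 0.0, 0.0])
    n = ca + _roll_x(np.array([-1.22, -0.79, 0.0]), STRAND1_TILT_DEG)
    c = ca + _roll_x(np.array([1.26, -0.82, 0.0]), STRAND1_TILT_DEG)
    o_dir = np.array([0.15, -0.98, 0.0]) / np.linalg.norm([0.15, -0.98, 0.0])
    o = c + 1.23 * _roll_x(o_dir, STRAND1_TILT_DEG)
    return _residue(aa, number, [("N", n), ("CA", ca), ("C", c), ("O", o)])


def _make_loop_backbone(seq: str, sep: float) -> list[ResidueRecord]:
    """Backbone of the hairpin: strand 1 (+x), 4-residue turn arc, strand 2 (-x)."""
    L = len(seq)
    n1 = max(5, (L + 1) // 2 - 2)
    n_turn = min(4, L - n1 - 1)
    if n_turn < 1:
        raise FixtureError(f"loop of length {L} too short for a hairpin")
    n2 = L - n1 - n_turn
    residues: list[ResidueRecord] = []
    for i in range(n1):
        residues.append(_strand1_residue(seq[i], 104 + i, i))
    x1e = (n1 - 1) * STRAND1_SPACING
    center = np.array([x1e + TURN_MARGIN, sep / 2.0, 0.0])
    radius = max(sep / 2.0, 2.2)
    for t in range(n_turn):
        phi = np.pi * (t + 1) / (n_turn + 1)
        ca = center + radius * np.array([np.sin(phi), -np.cos(phi), 0.0])
        tangent = np.array([np.cos(phi), np.sin(phi), 0.0])
        n = ca - 1.35 * tangent
        c = ca + 1.35 * tangent
        radial = np.array([np.sin(phi), -np.cos(phi), 0.0])
        o = c + 1.23 * radial
        residues.append(_residue(seq[n1 + t], 104 + n1 + t,
                                 [("N", n), ("CA", ca), ("C", c), ("O", o)]))
    for j in range(n2):
        ca = np.array([x1e - j * STRAND2_SPACING, sep, 0.0])
        n = ca + np.array([1.22, 0.79, 0.0])
        c = ca + np.array([-1.26, 0.82, 0.0])
        o = c + 1.23 * np.array([0.15, 0.98, 0.0]) / np.linalg.norm([0.15, 0.98, 0.0])
        residues.append(_residue(seq[n1 + n_turn + j], 104 + n1 + n_turn + j,
                                 [("N", n), ("CA", ca), ("C", c), ("O", o)]))
    return residues


def _stalk_frame(residues: list[ResidueRecord], stalk_index: int):
    res = residues[stalk_index]
    n = res.require_atom("N").coord
    ca = res.require_atom("CA").coord
    c = res.require_atom("C").coord
    return n, ca, c


def _countercurrent_ordinals(L: int) -> list[int]:
    start = max(int(np.ceil(L / 2)), 5)
    return list(range(start, L))


def _adjust_distance_a(residues: list[ResidueRecord], stalk_index: int,
                       target: float) -> None:
    """Shift the countercurrent strand along +/-y so that the minimum
    Cα(107)-carbonyl-C distance equals the target."""
    ca107 = residues[stalk_index].require_atom("CA").coord
    L = len(residues)
    ordinals = _countercurrent_ordinals(L)
    # shift only strand-2 residues (turn residues are kept out of reach)
    movable = [i for i in ordinals if residues[i].get_atom("CA") is not None
               and abs(residues[i].require_atom("CA").coord[2]) < 1e-9
               and residues[i].require_atom("CA").coord[1] > 1.0
               and residues[i].require_atom("N").coord[1]
               > residues[i].require_atom("CA").coord[1]]

    def min_dist(delta: float) -> float:
        best = np.inf
        for i in ordinals:
            c_atom = residues[i].get_atom("C")
            if c_atom is None:
                continue
            coord = c_atom.coord.copy()
            if i in movable:
                coord[1] += delta
            best = min(best, float(np.linalg.norm(coord - ca107)))
        return best

    lo, hi = -3.5, 8.0
    if not (min_dist(lo) <= target <= min_dist(hi)):
        raise FixtureError(f"distance-a target {target} out of reachable range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    for i in movable:
        for atom in residues[i].atoms:
            atom.coord[1] += delta


def _circle_point(center: np.ndarray, axis: np.ndarray, radius: float,
                  cos_t: float, repel: list[np.ndarray]) -> np.ndarray:
    """Point at angle ``arccos(cos_t)`` off ``axis`` on the sphere of given
    radius, choosing the azimuth that stays farthest from ``repel`` points."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(axis, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(axis, p1)
    sin_t = float(np.sqrt(max(0.0, 1.0 - cos_t**2)))
    best, best_score = None, -np.inf
    for phi in np.linspace(0.0, 2 * np.pi, 64, endpoint=False):
        point = center + radius * (cos_t * axis
                                   + sin_t * (np.cos(phi) * p1 + np.sin(phi) * p2))
        score = min(float(np.linalg.norm(point - q)) for q in repel)
        if score > best_score:
            best, best_score = point, score
    return best


def _oh_candidates(ca107: np.ndarray, og_ref: np.ndarray, dist_b: float,
                   n_azimuth: int = 16) -> list[np.ndarray]:
    """Candidate tyrosine hydroxyl positions: exactly ``dist_b`` from Cα(107)
    and within hydrogen-bond range (≥ probe clearance) of the reference Oγ
    site. When the two spheres intersect the full azimuth circle is offered;
    otherwise the single collinear point is the only solution."""
    axis = og_ref - ca107
    axis_len = float(np.linalg.norm(axis))
    axis /= axis_len
    d_want = float(np.clip(dist_b - axis_len, 2.96, 3.45))
    if not (abs(dist_b - d_want) <= axis_len <= dist_b + d_want):
        return [ca107 + dist_b * axis]
    cos_t = float(np.clip(
        (dist_b**2 + axis_len**2 - d_want**2) / (2 * dist_b * axis_len), -1, 1))
    sin_t = float(np.sqrt(max(0.0, 1.0 - cos_t**2)))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(axis, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(axis, p1)
    out = []
    for phi in np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False):
        out.append(ca107 + dist_b * (cos_t * axis
                                     + sin_t * (np.cos(phi) * p1
                                                + np.sin(phi) * p2)))
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform directions on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _flank_atoms(ca40: np.ndarray, oh: np.ndarray | None, og_ref: np.ndarray,
                 flank_seq: str) -> list[tuple[int, list[tuple[str, np.ndarray]]]]:
    """Atom layout of the framework strand given CA40 (and the OH, if any).

    The CZ-OH bond is tilted toward the Oγ site so that the hydroxyl presents
    an open C-O···O hydrogen-bond geometry instead of pointing its ring carbon
    into the cavity."""
    xhat = np.array([1.0, 0.0, 0.0])
    out = []
    for k, _aa in enumerate(flank_seq):
        number = 37 + k
        ca = ca40 + (number - 40) * 3.6 * xhat
        n = ca + np.array([-1.22, 0.0, 0.85])
        c = ca + np.array([1.26, 0.0, 0.88])
        o = c + np.array([0.0, 0.35, 1.18])
        specs = [("N", n), ("CA", ca), ("C", c), ("O", o)]
        if number == 40 and oh is not None:
            arm = oh - ca
            arm_len = float(np.linalg.norm(arm))
            arm /= arm_len
            u_og = og_ref - oh
            u_og /= np.linalg.norm(u_og)
            w = arm + 1.4 * u_og
            w /= np.linalg.norm(w)
            specs += [("CB", ca + 1.53 * arm), ("CG", ca + 2.9 * arm),
                      ("CZ", oh - 1.38 * w)]
            specs += [("OH", oh)]
        out.append((number, specs))
    return out


def _make_flank(ca107: np.ndarray, cb: np.ndarray, og_sites: list[np.ndarray],
                og_ref: np.ndarray, loop_atoms: list[np.ndarray],
                spec: HairpinSpec) -> list[ResidueRecord]:
    """Framework strand carrying residue 40 (Tyr or Ala) and residue 42.

    CA40 is searched on the sphere that makes CA42 land exactly at ``dist_c``
    from Cα(107), maximizing the clearance of every flank/arm atom from the
    loop backbone and all χ1 rotamer Oγ sites (so that the flank never blocks
    a serine placement it is not meant to block).
    """
    # include_y40 without an explicit dist_b target gets a default-length arm
    eff_dist_b = spec.dist_b if spec.dist_b is not None else (
        5.3 if spec.include_y40 else None)
    dist_c = spec.dist_c if spec.dist_c is not None else 4.9
    xhat = np.array([1.0, 0.0, 0.0])
    # clearance requirements: the rotamer sites must stay probe-accessible
    # (carbon vdW 1.70 + probe 1.4 + margin), the loop backbone merely
    # clash-free
    critical = np.array([og_ref, cb])
    other_sites = [s for s in og_sites
                   if float(np.linalg.norm(s - og_ref)) > 1e-9]
    semi = np.array(other_sites) if other_sites else critical
    loop_arr = np.array(list(loop_atoms))

    oh_options: list[np.ndarray | None] = [None]
    if eff_dist_b is not None:
        oh_options = list(_oh_candidates(ca107, og_ref, eff_dist_b))
    flank_seq = "SGV" + ("Y" if eff_dist_b is not None else "A") + "LTQV"

    def slack(ca40: np.ndarray, oh: np.ndarray | None) -> float:
        atoms = np.array([xyz for _num, specs
                          in _flank_atoms(ca40, oh, og_ref, flank_seq)
                          for nm, xyz in specs if nm != "OH"])
        d_crit = np.linalg.norm(atoms[:, None, :] - critical[None], axis=2).min()
        d_semi = np.linalg.norm(atoms[:, None, :] - semi[None], axis=2).min()
        d_loop = np.linalg.norm(atoms[:, None, :] - loop_arr[None], axis=2).min()
        return min(d_crit - 3.3, d_semi - 3.0, d_loop - 2.9)

    center_c = ca107 - 7.2 * xhat
    directions = _fibonacci_sphere(500)
    best = None
    best_score = -np.inf
    for relax_arm in (False, True):
        for oh in oh_options:
            for direction in directions:
                ca40 = center_c + dist_c * direction
                if oh is not None and not relax_arm:
                    arm_len = float(np.linalg.norm(oh - ca40))
                    if not (4.5 <= arm_len <= 8.5):
                        continue
                score = slack(ca40, oh)
                if score > best_score:
                    best, best_score = (ca40, oh), score
        if best is not None:
            break

    best_ca40, best_oh = best
    residues = []
    for (number, specs), aa in zip(
            _flank_atoms(best_ca40, best_oh, og_ref, flank_seq), flank_seq):
        residues.append(_residue(aa, number, specs))
    return residues


def make_hairpin(spec: HairpinSpec, seed: int = 0
                 ) -> tuple[StructureModel, dict]:
    """Build a hairpin stand-in structure and its manifest row.

    Deterministic for a given (spec, seed). Returns the structure and a
    manifest dict with keys ``pdb_id``, ``beta_chain``, ``cdr3_seq`` and
    ``y40_author_number`` suitable for IMGT anchoring.
    """
    seq = spec.loop_sequence
    residues = _make_loop_backbone(seq, spec.strand_separation)
    n, ca, c = _stalk_frame(residues, spec.stalk_index)
    cb = build_cb(n, ca, c)
    # reference rotamer: the staggered chi1 whose Og site can reach the
    # carbonyl of the following residue (the H-bond seen in CASS structures)
    c108_coord = residues[spec.stalk_index + 1].require_atom("C").coord
    candidates = {chi: serine_og(n, ca, cb, chi) for chi in (-60.0, 60.0, 180.0)}
    ref_chi1 = min(candidates,
                   key=lambda chi: float(np.linalg.norm(candidates[chi] - c108_coord)))
    if spec.serine_chi1 is not None:
        ref_chi1 = spec.serine_chi1
    og_ref = serine_og(n, ca, cb, ref_chi1)

    stalk_aa = seq[spec.stalk_index]
    if stalk_aa == "S":
        stalk = residues[spec.stalk_index]
        stalk.atoms.append(AtomRecord("CB", "C", cb))
        stalk.atoms.append(AtomRecord("OG", "O", og_ref))

    # orient the carbonyl of the residue after the stalk toward the reference
    # Oγ site so that a placed serine can hydrogen-bond to it (mirroring the
    # backbone O of residue 108 seen in serine-bearing crystal structures)
    res108 = residues[spec.stalk_index + 1]
    c108 = res108.require_atom("C").coord
    o108 = res108.require_atom("O")
    direction = og_ref - c108
    o108.coord[:] = c108 + 1.23 * direction / np.linalg.norm(direction)

    if spec.dist_a is not None:
        _adjust_distance_a(residues, spec.stalk_index, spec.dist_a)

    chains = []
    if spec.include_y40 or spec.dist_c is not None:
        loop_atoms = [a.coord for r in residues for a in r.atoms]
        flank = _make_flank(ca, cb, list(candidates.values()), og_ref,
                            loop_atoms, spec)
        chains.append(ChainModel(spec.chain_id, flank + residues))
    else:
        chains.append(ChainModel(spec.chain_id, residues))

    if spec.occlude_stalk:
        blockers = []
        for k, chi1 in enumerate((-60.0, 60.0, 180.0)):
            og_site = serine_og(n, ca, cb, chi1)
            blockers.append(_residue("A", 900 + k, [
                ("N", og_site + np.array([0.0, 0.0, 1.4])),
                ("CA", og_site + np.array([1.2, 0.0, 0.8])),
                ("C", og_site + np.array([2.0, 0.6, 0.0])),
                ("CB", og_site),
            ]))
        chains.append(ChainModel("Z", blockers))

    struct = StructureModel(pdb_id=spec.name[:4].upper() if len(spec.name) >= 4
                            else spec.name.upper(), models=[chains])
    manifest = {
        "tcr": spec.name,
        "pdb_id": struct.pdb_id,
        "beta_chain": spec.chain_id,
        "cdr3_seq": seq,
        "y40_author_number": 40 if (spec.include_y40 or spec.dist_c is not None) else "",
    }
    return struct, manifest


def make_table1_standin(tcr: str, cdr3_seq: str, dist_a: float,
                        dist_b: float | None, dist_c: float,
                        name: str | None = None, seed: int = 0
                        ) -> tuple[StructureModel, dict]:
    """Hairpin stand-in engineered to a published distance triple.

    Synthetic: this is not the deposited structure, only a geometric carrier
    whose measured (a, b, c) equal the published values, used to exercise the
    measurement pipeline end-to-end when the real coordinate files are not
    available.
    """
    spec = HairpinSpec(
        loop_sequence=cdr3_seq,
        include_y40=dist_b is not None,
        dist_a=dist_a,
        dist_b=dist_b,
        dist_c=dist_c,
        name=name or tcr,
    )
    struct, manifest = make_hairpin(spec, seed=seed)
    manifest["tcr"] = tcr
    return struct, manifest


# ---------------------------------------------------------------------------
# Gaussian trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianTrajSpec:
    """Gaussian-fluctuation ensemble with a known mass-weighted spectrum.

    ``variances`` (amu*A^2) may be a scalar (all internal modes equal) or a
    vector of length 3*n_atoms-6; the rigid-body subspace carries no variance,
    so per-frame superposition leaves the spectrum intact. ``rigid_motion``
    additionally applies a random rotation/translation to every frame.
    """

    n_atoms: int = 9
    n_frames: int = 500
    variances: float | tuple = 0.05
    seed: int = 0
    rigid_motion: bool = False
    temperature: float = 300.0

    def variance_vector(self) -> np.ndarray:
        n_modes = 3 * self.n_atoms - 6
        v = np.asarray(self.variances, dtype=float)
        if v.ndim == 0:
            v = np.full(n_modes, float(v))
        if v.shape != (n_modes,):
            raise FixtureError(f"need {n_modes} mode variances, got {v.shape}")
        if np.any(v <= 0):
            raise FixtureError("mode variances must be positive")
        return v


def _mean_backbone(n_atoms: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """A gently curved pseudo-backbone (names cycling N, CA, C)."""
    names = [("N", "CA", "C")[i % 3] for i in range(n_atoms)]
    masses = np.array([14.007 if nm == "N" else 12.011 for nm in names])
    t = np.arange(n_atoms, dtype=float)
    coords = np.stack([
        2.2 * np.cos(0.7 * t),
        2.2 * np.sin(0.7 * t),
        0.9 * t,
    ], axis=1)
    return coords, masses, names


def _rigid_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N x 6) of mass-weighted rigid-body motions."""
    n = coords.shape[0]
    com = np.average(coords, axis=0, weights=masses)
    rel = coords - com
    sm = np.sqrt(masses)
    cols = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = 1.0
        cols.append((v * sm[:, None]).ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        v = np.cross(np.broadcast_to(e, rel.shape), rel)
        cols.append((v * sm[:, None]).ravel())
    basis, _ = np.linalg.qr(np.stack(cols, axis=1))
    return basis


def make_gaussian_trajectory(spec: GaussianTrajSpec,
                             out_path: str | Path | None = None
                             ) -> tuple[TrajectoryEnsemble, float]:
    """Sample the ensemble and return it with its closed-form entropy.

    The analytic value evaluates the quasi-harmonic mode formula at the true
    spectrum; the estimate from :func:`quasiharmonic_entropy` converges to it
    as frames accumulate. ``out_path``, when given, also writes the frames as
    a multi-MODEL PDB (chain B, residues numbered from 104).
    """
    rng = np.random.default_rng(spec.seed)
    coords, masses, names = _mean_backbone(spec.n_atoms)
    variances = spec.variance_vector()
    n_modes = variances.size
    dof = 3 * spec.n_atoms

    rigid = _rigid_basis(coords, masses)
    rand = rng.standard_normal((dof, n_modes))
    full, _ = np.linalg.qr(np.hstack([rigid, rand]))
    internal = full[:, 6:6 + n_modes]

    z = rng.standard_normal((spec.n_frames, n_modes))
    x_mw = (z * np.sqrt(variances)) @ internal.T
    sm = np.repeat(np.sqrt(masses), 3)
    frames = coords[None, :, :] + (x_mw / sm).reshape(spec.n_frames, spec.n_atoms, 3)

    if spec.rigid_motion:
        from scipy.spatial.transform import Rotation
        for k in range(spec.n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(scale=2.0, size=3)
            com = frames[k].mean(axis=0)
            frames[k] = (frames[k] - com) @ R.T + com + t

    ensemble = TrajectoryEnsemble(
        frames=frames, atom_masses=masses,
        selection_label=f"gaussian[{spec.n_atoms} atoms]",
    )
    entropy = analytic_entropy(variances, spec.temperature)
    if out_path is not None:
        write_pdb(_trajectory_structure(frames, names), out_path)
    return ensemble, entropy


def _trajectory_structure(frames: np.ndarray, names: list[str]) -> StructureModel:
    models = []
    for frame in frames:
        residues = []
        res_atoms: list[tuple[str, np.ndarray]] = []
        res_no = 104
        for nm, xyz in zip(names, frame):
            res_atoms.append((nm, xyz))
            if nm == "C" or len(res_atoms) == 3:
                residues.append(_residue("G", res_no, res_atoms))
                res_atoms = []
                res_no += 1
        if res_atoms:
            residues.append(_residue("G", res_no, res_atoms))
        models.append([ChainModel("B", residues)])
    return StructureModel(pdb_id="TRAJ", models=models)


# ---------------------------------------------------------------------------
# toy V-gene FASTA
# ---------------------------------------------------------------------------

_NONMOTIF = "DEFHIKLMNPQRTVWY"  # avoids stray C/A that could re-anchor


def make_trbv_fasta(n_cass: int, n_casg: int, n_other: int, species: str,
                    path: str | Path, seed: int = 0) -> Path:
    """Write a toy V-gene C-terminus FASTA with an exact motif composition."""
    if min(n_cass, n_casg, n_other) < 0 or n_cass + n_casg + n_other < 1:
        raise FixtureError("counts must be non-negative and sum to at least 1")
    rng = np.random.default_rng(seed)
    entries = (["CASS"] * n_cass) + (["CASG"] * n_casg) + (["OTHER"] * n_other)
    lines = []
    for i, kind in enumerate(entries, start=1):
        prefix = "".join(rng.choice(list(_NONMOTIF), size=4))
        suffix = "".join(rng.choice(list(_NONMOTIF), size=2))
        if kind == "OTHER":
            motif = "CAW" + str(rng.choice(list("ST")))
        else:
            motif = kind
        lines.append(f">TRBVS{i}-{species}|{species}")
        lines.append(prefix + motif + suffix)
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
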