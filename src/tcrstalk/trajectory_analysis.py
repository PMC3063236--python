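"""Trajectory ensemble analysis: RMSD series and quasi-harmonic entropy.

A trajectory is an ordered set of frames for a fixed atom selection (here,
typically the CDR3beta backbone N, Cα, C atoms), read from a multi-MODEL PDB
file standing in for MD engine output. The configurational entropy estimator
is the quasi-harmonic (covariance-matrix) one: after per-frame least-squares
superposition, the mass-weighted covariance of atomic fluctuations is
diagonalized and each eigenmode is treated as a quantum harmonic oscillator at
the given temperature,

    omega_k = sqrt(kB*T / lambda_k),   alpha_k = hbar*omega_k / (kB*T),
    S = R * sum_k [ alpha_k/(exp(alpha_k)-1) - ln(1-exp(-alpha_k)) ],

with lambda_k in amu*A^2 and S reported in cal mol^-1 K^-1. Near-zero
eigenvalues (the six rigid-body modes removed by superposition, plus any
numerically empty mode) are excluded by a configurable floor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import (
    ATOMIC_MASSES,
    ATOMIC_MASS_KG,
    BOLTZMANN_J_PER_K,
    GAS_CONSTANT_CAL,
    HBAR_J_S,
)
from .geometry_core import rmsd_between, superpose
from .structure_model import StructureModel, parse_structure

EIGENVALUE_FLOOR = 1e-8  # amu*A^2


class TrajectoryError(Exception):
    pass


@dataclass
class TrajectoryEnsemble:
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    atom_masses: np.ndarray     # (n_atoms,), amu
    selection_label: str = ""
    timestep: float = 1.0       # ps per frame (metadata only)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.atom_masses = np.asarray(self.atom_masses, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError("frames must have shape (n_frames, n_atoms, 3)")
        if self.atom_masses.shape != (self.frames.shape[1],):
            raise TrajectoryError("one mass per atom required")
        if np.any(self.atom_masses <= 0):
            raise TrajectoryError("atom masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class RmsdSeries:
    values: np.ndarray
    reference_label: str = "initial structure"


@dataclass
class EntropyResult:
    eigenvalues: np.ndarray      # amu*A^2, decreasing
    frequencies: np.ndarray      # rad/s, for the modes used
    entropy: float               # cal mol^-1 K^-1
    temperature: float
    n_modes_used: int


@dataclass(frozen=True)
class Selection:
    """Atom selection: chain, inclusive residue number range, atom names."""
    chain_id: str
    res_range: tuple[int, int]
    atom_names: tuple[str, ...] = ("N", "CA", "C")

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse e.g. ``"B:104-119@N,CA,C"``."""
        m = re.fullmatch(r"(\w):(\d+)-(\d+)(?:@([\w,]+))?", text.strip())
        if not m:
            raise TrajectoryError(f"cannot parse selection {text!r}")
        names = tuple(m.group(4).split(",")) if m.group(4) else ("N", "CA", "C")
        return cls(m.group(1), (int(m.group(2)), int(m.group(3))), names)

    def resolve(self, chains) -> list[tuple[int, str]]:
        """(residue number, atom name) keys selected, in chain order."""
        keys = []
        for ch in chains:
            if ch.chain_id != self.chain_id:
                continue
            for res in ch.residues:
                if self.res_range[0] <= res.number <= self.res_range[1]:
                    for name in self.atom_names:
                        if res.get_atom(name) is not None:
                            keys.append((res.number, name))
        return keys


def read_trajectory(source: str | Path | StructureModel,
                    selection: Selection | str,
                    timestep: float = 1.0) -> TrajectoryEnsemble:
    """Extract an atom selection from every model of a multi-MODEL PDB file.

    The selection must resolve to the same atoms in every model; a mismatch is
    reported with the offending model number (1-based, as in the file).
    """
    struct = source if isinstance(source, StructureModel) else parse_structure(source)
    if isinstance(selection, str):
        selection = Selection.from_string(selection)
    if struct.n_models < 2:
        raise TrajectoryError("trajectory needs at least 2 MODEL blocks")
    ref_keys = selection.resolve(struct.models[0])
    if not ref_keys:
        raise TrajectoryError(f"selection matches no atoms in model 1")
    frames = []
    masses = None
    for imodel, chains in enumerate(struct.models, start=1):
        keys = selection.resolve(chains)
        if keys != ref_keys:
            raise TrajectoryError(
                f"selection resolves differently in model {imodel} "
                f"({len(keys)} atoms vs {len(ref_keys)} in model 1)"
            )
        coords = []
        elems = []
        for ch in chains:
            if ch.chain_id != selection.chain_id:
                continue
            for res in ch.residues:
                if selection.res_range[0] <= res.number <= selection.res_range[1]:
                    for name in selection.atom_names:
                        atom = res.get_atom(name)
                        if atom is not None:
                            coords.append(atom.coord)
                            elems.append(atom.element)
        frames.append(np.array(coords))
        if masses is None:
            masses = np.array([ATOMIC_MASSES[e] for e in elems])
    label = f"{selection.chain_id}:{selection.res_range[0]}-{selection.res_range[1]}" \
            f"@{','.join(selection.atom_names)}"
    return TrajectoryEnsemble(frames=np.array(frames), atom_masses=masses,
                              selection_label=label, timestep=timestep)


def rmsd_series(traj: TrajectoryEnsemble, reference: np.ndarray,
                fit_indices: np.ndarray | None = None,
                report_indices: np.ndarray | None = None,
                reference_label: str = "initial structure") -> RmsdSeries:
    """Per-frame RMSD to a reference after least-squares fitting.

    Each frame is superposed onto the reference using ``fit_indices`` (all
    atoms by default) and the RMSD is evaluated over ``report_indices``.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise TrajectoryError("reference must match the trajectory atom count")
    fit = np.arange(traj.n_atoms) if fit_indices is None else np.asarray(fit_indices)
    rep = np.arange(traj.n_atoms) if report_indices is None else np.asarray(report_indices)
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        sup = superpose(frame[fit], ref[fit])
        values[k] = rmsd_between(sup.apply(frame)[rep], ref[rep])
    return RmsdSeries(values=values, reference_label=reference_label)


def align_to_mean(frames: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Superpose all frames onto their (iteratively refined) mean structure."""
    aligned = np.array(frames, dtype=float, copy=True)
    ref = aligned[0]
    for _ in range(n_iter):
        for k in range(aligned.shape[0]):
            aligned[k] = superpose(aligned[k], ref).apply(aligned[k])
        ref = aligned.mean(axis=0)
    for k in range(aligned.shape[0]):
        aligned[k] = superpose(aligned[k], ref).apply(aligned[k])
    return aligned


def _alpha(lambdas: np.ndarray, temperature: float) -> np.ndarray:
    lam_si = lambdas * ATOMIC_MASS_KG * 1e-20  # kg m^2
    return HBAR_J_S / np.sqrt(BOLTZMANN_J_PER_K * temperature * lam_si)


def mode_entropies(lambdas: np.ndarray, temperature: float) -> np.ndarray:
    """Per-mode quantum harmonic oscillator entropies (cal mol^-1 K^-1)."""
    lambdas = np.asarray(lambdas, dtype=float)
    a = _alpha(lambdas, temperature)
    return GAS_CONSTANT_CAL * (a / np.expm1(a) - np.log1p(-np.exp(-a)))


def analytic_entropy(lambdas, temperature: float = 300.0) -> float:
    """Closed-form quasi-harmonic entropy at known mode variances (amu*A^2)."""
    lambdas = np.asarray(lambdas, dtype=float)
    lambdas = lambdas[lambdas > EIGENVALUE_FLOOR]
    if lambdas.size == 0:
        return 0.0
    return float(np.sum(mode_entropies(lambdas, temperature)))


def quasiharmonic_entropy(traj: TrajectoryEnsemble, temperature: float = 300.0,
                          superpose_frames: bool = True,
                          eigenvalue_floor: float = EIGENVALUE_FLOOR) -> EntropyResult:
    """Quasi-harmonic entropy of a trajectory's mass-weighted fluctuations."""
    if traj.n_frames < 2:
        raise TrajectoryError("entropy needs at least 2 frames")
    if traj.n_frames < 3 * traj.n_atoms:
        warnings.warn(
            f"only {traj.n_frames} frames for {3 * traj.n_atoms} degrees of "
            "freedom; covariance estimate may be rank-deficient"
        )
    frames = align_to_mean(traj.frames) if superpose_frames else traj.frames
    disp = frames - frames.mean(axis=0)
    weights = np.repeat(np.sqrt(traj.atom_masses), 3)
    x = disp.reshape(traj.n_frames, -1) * weights
    cov = np.cov(x, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    used = eig[eig > eigenvalue_floor]
    entropy = float(np.sum(mode_entropies(used, temperature))) if used.size else 0.0
    lam_si = used * ATOMIC_MASS_KG * 1e-20
    freqs = (np.sqrt(BOLTZMANN_J_PER_K * temperature / lam_si)
             if used.size else np.array([]))
    return EntropyResult(eigenvalues=eig, frequencies=freqs, entropy=entropy,
                         temperature=temperature, n_modes_used=int(used.size))


def entropy_difference(traj_wt: TrajectoryEnsemble, traj_mut: TrajectoryEnsemble,
                       temperature: float = 300.0) -> float:
    """S(wt) - S(mutant), positive when the mutant ensemble is stiffer."""
    s_wt = quasiharmonic_entropy(traj_wt, temperature).entropy
    s_mut = quasiharmonic_entropy(traj_mut, temperature).entropy
    return s_wt - s_mut
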