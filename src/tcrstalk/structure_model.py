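"""Parse and represent protein structures; anchor IMGT positions on author numbering.

The in-memory model is deliberately small: atoms, residues, chains, and one or
more models (multi-MODEL PDB files are treated as trajectory frames). Parsing is
delegated to gemmi; only polymer ATOM records are retained (HETATM groups and
waters are dropped). Writing emits minimal fixed-width PDB text so that
coordinates round-trip byte-identically at the standard 8.3 field width.

IMGT anchoring locates the CDR3beta on a chosen beta chain from its sequence:
position 104 is the conserved cysteine opening the CDR3, position 107 the
fourth residue of the motif (the G/S site studied here). The framework tyrosine
at IMGT 40 and the strand residue at IMGT 42 are located through an
author-numbering hint supplied per structure in a manifest, because author
numbering of deposited TCR structures does not follow IMGT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class StructureError(Exception):
    """Base class for structure parsing/anchoring problems."""


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class AnchorError(StructureError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), angstrom
    serial: int = 0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class ResidueRecord:
    aa: str                  # one-letter code, 'X' for nonstandard
    number: int              # author residue number
    icode: str = ""          # insertion code, part of residue identity
    name3: str = "UNK"
    atoms: list[AtomRecord] = field(default_factory=list)

    def get_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require_atom(self, name: str) -> AtomRecord:
        atom = self.get_atom(name)
        if atom is None:
            raise StructureError(
                f"residue {self.name3} {self.number}{self.icode}: atom {name} missing"
            )
        return atom

    @property
    def label(self) -> str:
        return f"{self.name3}{self.number}{self.icode}"


@dataclass
class ChainModel:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue_by_number(self, number: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class StructureModel:
    """A parsed structure: ≥1 model, each a list of chains.

    ``chains`` exposes the first model; additional models correspond to
    MODEL/ENDMDL blocks (trajectory frames).
    """

    pdb_id: str
    models: list[list[ChainModel]]

    @property
    def chains(self) -> list[ChainModel]:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def get_chain(self, chain_id: str, model: int = 0) -> ChainModel:
        for ch in self.models[model]:
            if ch.chain_id == chain_id:
                return ch
        raise StructureError(f"{self.pdb_id}: no chain {chain_id!r} in model {model}")

    def all_atoms(self, model: int = 0):
        """Yield (chain, residue, atom) triples for one model."""
        for ch in self.models[model]:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch, res, atom


@dataclass
class ImgtAnchor:
    """CDR3beta and framework reference residues of one beta chain.

    ``pos40`` is set only when the residue located by the author-numbering hint
    is a tyrosine (it carries the hydroxyl used for distance b); ``res40`` holds
    whatever residue sits at that position so that ``pos42`` (two residues
    downstream in chain order) remains defined even when the tyrosine is absent.
    """

    beta_chain_id: str
    cdr3_sequence: str
    pos104: ResidueRecord
    pos107: ResidueRecord
    loop_residues: list[ResidueRecord]
    res40: ResidueRecord | None = None
    pos40: ResidueRecord | None = None   # the Tyr, when present
    pos42: ResidueRecord | None = None

    @property
    def y40_present(self) -> bool:
        return self.pos40 is not None


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip().upper()
    if not el:
        el = atom.name.strip()[0]
    return el


def parse_structure(path: str | Path) -> StructureModel:
    """Parse a PDB-format file into a :class:`StructureModel`.

    HETATM groups and waters are excluded; where alternate locations exist the
    first conformer (altloc A) is kept and the choice logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if any(
        atom.altloc not in ("", "\x00", "A")
        for model in st for chain in model for res in chain for atom in res
    ):
        warnings.warn(f"{path.name}: alternate locations present; keeping altloc A")
    st.remove_alternative_conformations()

    models: list[list[ChainModel]] = []
    for model in st:
        chains: list[ChainModel] = []
        for chain in model:
            residues: list[ResidueRecord] = []
            for res in chain:
                if res.het_flag != "A" or res.is_water():
                    continue
                rec = ResidueRecord(
                    aa=THREE_TO_ONE.get(res.name, "X"),
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name3=res.name,
                )
                seen: set[str] = set()
                for atom in res:
                    name = atom.name.strip()
                    if name in seen:
                        continue
                    seen.add(name)
                    rec.atoms.append(AtomRecord(
                        name=name,
                        element=_element_of(atom),
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        serial=atom.serial,
                    ))
                if rec.atoms:
                    residues.append(rec)
            if residues:
                chains.append(ChainModel(chain.name, residues))
        if chains:
            models.append(chains)
    if not models:
        raise EmptyStructureError(f"{path}: no protein ATOM records found")
    return StructureModel(pdb_id=path.stem.upper()[:4] or path.stem, models=models)


def format_atom_line(serial: int, atom: AtomRecord, res: ResidueRecord,
                     chain_id: str) -> str:
    """One fixed-width ATOM record (coordinates at the standard 8.3 width)."""
    name = atom.name
    # standard PDB name justification: element right-aligned in cols 13-14
    padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {padded:<4s}{'':1s}{res.name3:>3s} {chain_id:1s}"
        f"{res.number:>4d}{res.icode or ' ':1s}   "
        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_pdb(struct: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal PDB text (multi-MODEL when n_models>1)."""
    lines: list[str] = []
    multi = struct.n_models > 1
    for imodel, chains in enumerate(struct.models, start=1):
        if multi:
            lines.append(f"MODEL {imodel:>8d}")
        serial = 0
        for chain in chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(format_atom_line(serial, atom, res, chain.chain_id))
            lines.append(f"TER   {serial + 1:>5d}      {chain.residues[-1].name3:>3s} "
                         f"{chain.chain_id:1s}{chain.residues[-1].number:>4d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def anchor_imgt(struct: StructureModel, beta_chain_id: str, cdr3_sequence: str,
                y40_author_number: int | None = None, y40_window: int = 2,
                model: int = 0) -> ImgtAnchor:
    """Anchor IMGT positions 104/107 (and 40/42 when hinted) on a beta chain.

    ``cdr3_sequence`` must start with the conserved cysteine and occur exactly
    once in the chain sequence. The loop extends from the match through author
    number 119 when trailing residues are contiguous in chain order.
    """
    if not cdr3_sequence or cdr3_sequence[0] != "C":
        raise AnchorError(f"CDR3 sequence must start with C, got {cdr3_sequence!r}")
    if len(cdr3_sequence) < 4:
        raise AnchorError("CDR3 sequence shorter than 4 residues")
    chain = struct.get_chain(beta_chain_id, model=model)
    seq = chain.sequence
    n_hits = seq.count(cdr3_sequence)
    if n_hits == 0:
        raise AnchorError(
            f"{struct.pdb_id} chain {beta_chain_id}: CDR3 {cdr3_sequence} not found"
        )
    if n_hits > 1:
        raise AnchorError(
            f"{struct.pdb_id} chain {beta_chain_id}: CDR3 {cdr3_sequence} ambiguous "
            f"({n_hits} matches)"
        )
    start = seq.index(cdr3_sequence)
    end = start + len(cdr3_sequence)  # exclusive
    pos104 = chain.residues[start]
    if pos104.aa != "C":
        raise AnchorError(f"position 104 residue is {pos104.aa}, expected C")
    pos107 = chain.residues[start + 3]

    loop = list(chain.residues[start:end])
    # extend through IMGT/author 119 while contiguous in chain order
    i = end
    while i < len(chain.residues) and loop[-1].number < 119:
        nxt = chain.residues[i]
        if nxt.number != loop[-1].number + 1:
            break
        loop.append(nxt)
        i += 1

    res40 = pos40 = pos42 = None
    if y40_author_number is not None:
        window = [
            (idx, r) for idx, r in enumerate(chain.residues)
            if abs(r.number - y40_author_number) <= y40_window and idx < start
        ]
        tyrs = [(idx, r) for idx, r in window if r.aa == "Y"]
        if len(tyrs) == 1:
            idx40, res40 = tyrs[0]
            pos40 = res40
        elif window:
            # residue exists at the hinted position but is not (uniquely) a Tyr
            exact = [(idx, r) for idx, r in window if r.number == y40_author_number]
            idx40, res40 = exact[0] if exact else window[0]
        else:
            idx40 = None
        if res40 is not None and idx40 is not None and idx40 + 2 < len(chain.residues):
            pos42 = chain.residues[idx40 + 2]
    return ImgtAnchor(
        beta_chain_id=beta_chain_id,
        cdr3_sequence=cdr3_sequence,
        pos104=pos104,
        pos107=pos107,
        loop_residues=loop,
        res40=res40,
        pos40=pos40,
        pos42=pos42,
    )
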