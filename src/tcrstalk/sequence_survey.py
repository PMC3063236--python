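"""Census of TRBV C-terminal motifs (CASS vs CASG at IMGT 104-107).

Most TCR beta-chain V genes end in a conserved CASS motif opening the CDR3;
a single V gene per species (mouse TRBV13-2, human TRBV12-5) carries CASG
instead. This module classifies V-gene C-terminal protein sequences by that
motif and tallies per-species counts and rounded percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

VALID_SPECIES = ("mouse", "human")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
ANCHOR_WINDOW = 12  # residues from the C-terminus searched for the C104 anchor


class SurveyError(Exception):
    pass


@dataclass
class VGeneRecord:
    gene_name: str
    species: str
    cterm_seq: str

    def __post_init__(self):
        if self.species not in VALID_SPECIES:
            raise SurveyError(
                f"{self.gene_name}: species must be one of {VALID_SPECIES}, "
                f"got {self.species!r}"
            )
        seq = self.cterm_seq.upper()
        if not seq or not set(seq) <= AA_ALPHABET:
            raise SurveyError(f"{self.gene_name}: invalid amino-acid sequence")
        self.cterm_seq = seq


@dataclass
class SpeciesCensus:
    species: str
    n_total: int = 0
    n_cass: int = 0
    n_casg: int = 0
    n_other: int = 0

    @property
    def percent_cass(self) -> int:
        return round(100 * self.n_cass / self.n_total) if self.n_total else 0

    @property
    def percent_casg(self) -> int:
        return round(100 * self.n_casg / self.n_total) if self.n_total else 0


@dataclass
class MotifCensus:
    per_species: dict[str, SpeciesCensus] = field(default_factory=dict)

    def species(self, name: str) -> SpeciesCensus:
        return self.per_species[name]


def read_vgene_fasta(path: str | Path) -> list[VGeneRecord]:
    """Read V-gene C-termini from FASTA with ``>name|species`` headers."""
    path = Path(path)
    records: list[VGeneRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = rec.id.split("|")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise SurveyError(
                f"{path.name}, entry {i}: header must be 'name|species', got {rec.id!r}"
            )
        name, species = parts
        if name in seen:
            raise SurveyError(f"{path.name}, entry {i}: duplicate gene name {name!r}")
        seen.add(name)
        records.append(VGeneRecord(gene_name=name, species=species,
                                   cterm_seq=str(rec.seq)))
    if not records:
        raise SurveyError(f"{path.name}: no FASTA records found")
    return records


def classify_motif(rec: VGeneRecord) -> str:
    """Classify one V-gene C-terminus as ``CASS``, ``CASG`` or ``other``.

    The anchoring C104 is located as the last ``CA`` dinucleotide-style match
    (C followed by A) within the final residues of the sequence; positions
    104-107 are that cysteine and the next three residues. Sequences without
    an anchor are counted as other, with a warning.
    """
    seq = rec.cterm_seq
    window_start = max(0, len(seq) - ANCHOR_WINDOW)
    anchor = -1
    for i in range(window_start, len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "A":
            anchor = i
    if anchor < 0 or anchor + 4 > len(seq):
        warnings.warn(f"{rec.gene_name}: no C104 anchor found; counted as other")
        return "other"
    motif = seq[anchor:anchor + 4]
    if motif == "CASS":
        return "CASS"
    if motif == "CASG":
        return "CASG"
    return "other"


def census(records: list[VGeneRecord]) -> MotifCensus:
    """Per-species CASS/CASG/other tallies with integer-rounded percentages."""
    if not records:
        raise SurveyError("census: no records")
    result = MotifCensus()
    for rec in records:
        sc = result.per_species.setdefault(rec.species, SpeciesCensus(rec.species))
        sc.n_total += 1
        kind = classify_motif(rec)
        if kind == "CASS":
            sc.n_cass += 1
        elif kind == "CASG":
            sc.n_casg += 1
        else:
            sc.n_other += 1
    return result
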