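"""The CDR3beta stalk distance triple (a, b, c) and its group statistics.

Distance a: Cα of the residue at IMGT 107 to the nearest backbone carbonyl
carbon in the countercurrent (J-encoded, descending) strand of the CDR3.
Distance b: Cα(107) to the side-chain hydroxyl oxygen of the framework Y40,
NA when that tyrosine is absent. Distance c: Cα(107) to Cα of the strand
residue at IMGT 42. Structures with a glycine at 107 (the TRBV13-2 / TRBV12-5
CASG motif) are compared as a group against serine-bearing (CASS-type)
structures via NA-aware means and sample standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry_core import distance
from .structure_model import ImgtAnchor, StructureModel


class MeasurementError(Exception):
    pass


@dataclass
class StalkDistances:
    tcr_name: str
    pdb_id: str
    cdr3_seq: str
    is_g107: bool
    dist_a: float
    dist_b: float | None   # None encodes NA (Y40 absent)
    dist_c: float | None
    partner_a: str = ""    # label of the carbonyl partner chosen for distance a

    def as_row(self) -> dict:
        return {
            "tcr": self.tcr_name,
            "trbv13_2": "Y" if self.is_g107 else "N",
            "pdb_id": self.pdb_id,
            "cdr3_seq": self.cdr3_seq,
            "dist_a": round(self.dist_a, 2),
            "dist_b": round(self.dist_b, 2) if self.dist_b is not None else None,
            "dist_c": round(self.dist_c, 2) if self.dist_c is not None else None,
            "partner_a": self.partner_a,
        }


@dataclass
class GroupSummary:
    group: str            # "G107" or "S107"
    n: int
    mean_a: float | None
    sd_a: float | None
    mean_b: float | None
    sd_b: float | None
    mean_c: float | None
    sd_c: float | None


def classify_position107(cdr3_seq: str) -> str:
    """Classify a CDR3beta sequence by its 4th residue (IMGT 107)."""
    if len(cdr3_seq) < 4:
        raise ValueError("CDR3 sequence must have at least 4 residues")
    if cdr3_seq[0] != "C":
        raise ValueError("CDR3 sequence must start with the conserved C104")
    res = cdr3_seq[3]
    if res == "G":
        return "G107"
    if res == "S":
        return "S107"
    return "other"


def countercurrent_candidates(anchor: ImgtAnchor):
    """Residues of the descending (J-encoded) strand eligible as distance-a
    partners: loop residues from the apex (ordinal ceil(L/2) within the match)
    onward, excluding IMGT 104-108."""
    L = len(anchor.cdr3_sequence)
    start_ordinal = math.ceil(L / 2)
    return [r for i, r in enumerate(anchor.loop_residues)
            if i >= start_ordinal and i > 4]


def measure_stalk(struct: StructureModel, anchor: ImgtAnchor,
                  tcr_name: str = "") -> StalkDistances:
    """Compute the (a, b, c) distance triple for one anchored structure."""
    ca107 = anchor.pos107.get_atom("CA")
    if ca107 is None:
        raise MeasurementError(
            f"{struct.pdb_id}: residue 107 ({anchor.pos107.label}) lacks a CA atom"
        )
    candidates = []
    for res in countercurrent_candidates(anchor):
        c_atom = res.get_atom("C")
        if c_atom is not None:
            candidates.append((distance(ca107.coord, c_atom.coord), res))
    if not candidates:
        raise MeasurementError(
            f"{struct.pdb_id}: no countercurrent carbonyl carbons available"
        )
    candidates.sort(key=lambda t: t[0])
    dist_a, partner = candidates[0]

    dist_b = None
    if anchor.pos40 is not None:
        oh = anchor.pos40.get_atom("OH")
        if oh is not None:
            dist_b = distance(ca107.coord, oh.coord)

    dist_c = None
    if anchor.pos42 is not None:
        ca42 = anchor.pos42.get_atom("CA")
        if ca42 is not None:
            dist_c = distance(ca107.coord, ca42.coord)

    return StalkDistances(
        tcr_name=tcr_name or struct.pdb_id,
        pdb_id=struct.pdb_id,
        cdr3_seq=anchor.cdr3_sequence,
        is_g107=classify_position107(anchor.cdr3_sequence) == "G107",
        dist_a=dist_a,
        dist_b=dist_b,
        dist_c=dist_c,
        partner_a=partner.label,
    )


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return mean, sd


def summarize_groups(rows: list[StalkDistances]) -> tuple[GroupSummary, GroupSummary]:
    """NA-aware per-group mean and sample SD (n-1 denominator) of a, b, c."""
    if not rows:
        raise ValueError("summarize_groups: no rows")
    out = []
    for name, keep in (("G107", True), ("S107", False)):
        grp = [r for r in rows if r.is_g107 is keep]
        mean_a, sd_a = _mean_sd([r.dist_a for r in grp])
        mean_b, sd_b = _mean_sd([r.dist_b for r in grp])
        mean_c, sd_c = _mean_sd([r.dist_c for r in grp])
        out.append(GroupSummary(group=name, n=len(grp), mean_a=mean_a, sd_a=sd_a,
                                mean_b=mean_b, sd_b=sd_b, mean_c=mean_c, sd_c=sd_c))
    return out[0], out[1]


def rows_to_frame(rows: list[StalkDistances]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in rows])


def summaries_to_frame(g: GroupSummary, s: GroupSummary) -> pd.DataFrame:
    def fmt(summary: GroupSummary) -> dict:
        row = {"group": summary.group, "n": summary.n}
        for key in ("mean_a", "sd_a", "mean_b", "sd_b", "mean_c", "sd_c"):
            val = getattr(summary, key)
            row[key] = round(val, 2) if val is not None else None
        return row
    return pd.DataFrame([fmt(g), fmt(s)])


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """The published per-TCR distance table shipped with the package.

    Columns: tcr, trbv13_2 (Y/N), pdb_id, cdr3_seq, dist_a, dist_b, dist_c;
    NA marks structures whose beta chain lacks the framework tyrosine.
    """
    if path is None:
        ref = resources.files("tcrstalk.data") / "table1.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", na_values=["NA"])
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def reference_rows(path: str | Path | None = None) -> list[StalkDistances]:
    """Published distances as StalkDistances rows (for group statistics)."""
    df = load_reference_table(path)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(StalkDistances(
            tcr_name=rec.tcr,
            pdb_id=rec.pdb_id,
            cdr3_seq=rec.cdr3_seq,
            is_g107=rec.trbv13_2 == "Y",
            dist_a=float(rec.dist_a),
            dist_b=None if pd.isna(rec.dist_b) else float(rec.dist_b),
            dist_c=None if pd.isna(rec.dist_c) else float(rec.dist_c),
        ))
    return rows
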