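"""Peptide-to-protein mapping and percent sequence coverage.

Sequence coverage — the percentage of a protein's residues covered by at
least one identified peptide — is the readout of the limited-proteolysis
screen: a protein that is degraded by pronase loses coverage, and a protein
protected by a bound ligand regains it. This module maps peptide evidence
onto protein sequences and computes per-protein, per-condition coverage.

Coordinates are 1-based inclusive throughout, following proteomics
convention. Isoleucine and leucine are treated as distinct by default (they
are isobaric in MS; enable ``il_equivalent`` when mapping real search-engine
output).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EvidenceError

CONDITIONS = ("control", "pronase", "pronase_drug")

EVIDENCE_COLUMNS = ["condition", "protein_id", "peptide", "start", "end"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise EvidenceError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideMatch:
    """One peptide located on a protein, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise EvidenceError(
                f"invalid interval [{self.start}, {self.end}] on {self.protein_id!r}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a peptide-evidence TSV (condition, protein_id, peptide[, start, end])."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str})
    missing = {"condition", "protein_id", "peptide"} - set(df.columns)
    if missing:
        raise EvidenceError(f"evidence table lacks required columns: {sorted(missing)}")
    return df


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _canon(seq: str, il_equivalent: bool) -> str:
    return seq.replace("L", "I") if il_equivalent else seq


def map_peptides(
    protein: ProteinRecord,
    peptides: Sequence[str],
    il_equivalent: bool = False,
) -> tuple[list[PeptideMatch], list[str]]:
    """Locate every exact occurrence of each peptide in the protein.

    All occurrences are reported, including overlapping ones. Peptides with
    no occurrence are returned in the rejects list rather than dropped.
    """
    haystack = _canon(protein.sequence, il_equivalent)
    matches: list[PeptideMatch] = []
    rejects: list[str] = []
    for pep in peptides:
        if not pep:
            raise EvidenceError("empty peptide string in evidence")
        needle = _canon(pep, il_equivalent)
        found = False
        pos = haystack.find(needle)
        while pos != -1:
            matches.append(
                PeptideMatch(protein.id, start=pos + 1, end=pos + len(pep), peptide=pep)
            )
            found = True
            pos = haystack.find(needle, pos + 1)
        if not found:
            rejects.append(pep)
    return matches, rejects


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted, disjoint list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def compute_coverage(protein_length: int, matches: Iterable[PeptideMatch]) -> float:
    """Percent of residues covered by the union of matched intervals."""
    if protein_length <= 0:
        raise EvidenceError("protein length must be positive")
    intervals = []
    for m in matches:
        if m.end > protein_length:
            raise EvidenceError(
                f"match [{m.start}, {m.end}] exceeds protein length {protein_length}"
            )
        intervals.append((m.start, m.end))
    covered = sum(end - start + 1 for start, end in merge_intervals(intervals))
    return 100.0 * covered / protein_length


def coverage_table(
    proteins: Sequence[ProteinRecord],
    evidence: pd.DataFrame,
    il_equivalent: bool = False,
) -> pd.DataFrame:
    """Per-protein, per-condition percent coverage from an evidence table.

    Rows with start/end are validated against the sequence; rows without are
    mapped (all occurrences). Every (protein, condition) pair over the full
    proteome x observed-condition grid appears in the output, with proteins
    lacking evidence in a condition assigned 0% coverage.
    """
    by_id = {p.id: p for p in proteins}
    conditions = list(pd.unique(evidence["condition"]))
    matches: dict[tuple[str, str], list[PeptideMatch]] = {}
    has_coords = {"start", "end"} <= set(evidence.columns)
    for row in evidence.itertuples(index=False):
        prot = by_id.get(row.protein_id)
        if prot is None:
            raise EvidenceError(f"evidence references unknown protein {row.protein_id!r}")
        key = (row.protein_id, row.condition)
        if has_coords and pd.notna(row.start) and pd.notna(row.end):
            m = PeptideMatch(prot.id, int(row.start), int(row.end), row.peptide)
            seg = _canon(prot.sequence[m.start - 1 : m.end], il_equivalent)
            if m.end > prot.length or seg != _canon(m.peptide, il_equivalent):
                raise EvidenceError(
                    f"peptide {m.peptide!r} does not match {prot.id} at "
                    f"[{m.start}, {m.end}]"
                )
            matches.setdefault(key, []).append(m)
        else:
            found, rejected = map_peptides(prot, [row.peptide], il_equivalent)
            if rejected:
                raise EvidenceError(
                    f"peptide {row.peptide!r} not found in protein {prot.id}"
                )
            matches.setdefault(key, []).extend(found)
    rows = [
        {
            "protein_id": p.id,
            "condition": cond,
            "coverage": compute_coverage(p.length, matches.get((p.id, cond), [])),
        }
        for p in proteins
        for cond in conditions
    ]
    return pd.DataFrame(rows, columns=["protein_id", "condition", "coverage"])
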