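"""Protein sequence I/O, residue classification and basic statistics.

Records are plain dataclasses; FASTA reading/writing goes through Bio.SeqIO.
Molecular weights use average (not monoisotopic) residue masses, the
convention behind "predicted molecular weight" figures for whole proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue masses in Da (ExPASy convention); water added once per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

GAP = "-"


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the record invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an opaque accession-style identifier."""

    id: str
    sequence: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if GAP in self.sequence:
            raise ValueError(f"record {self.id!r}: gap characters not allowed")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment (rows of equal length)."""

    rows: tuple["AlignedRow", ...]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].sequence)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r.sequence[j] for r in self.rows)

    def ungapped(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(r.id, r.sequence.replace(GAP, ""), r.description)
            for r in self.rows
        ]


@dataclass(frozen=True)
class AlignedRow:
    """One alignment row; gaps permitted, ungapping must leave residues."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence.replace(GAP, ""):
            raise ValueError(f"row {self.id!r}: all-gap sequence")


@dataclass(frozen=True)
class ResidueClassTable:
    """Residue classes for degenerate motif matching.

    Glycine is fixed; the polar/hydrophobic split is configurable because
    published class labels rarely enumerate their sets.
    """

    polar: frozenset[str] = frozenset("CDEHKNQRSTY")
    hydrophobic: frozenset[str] = frozenset("AFILMVW")
    glycine: frozenset[str] = frozenset("G")

    def __post_init__(self):
        if self.glycine != frozenset("G"):
            raise ValueError("glycine class is fixed to {G}")
        if self.polar & self.hydrophobic:
            raise ValueError(
                f"polar/hydrophobic overlap: {sorted(self.polar & self.hydrophobic)}"
            )


def residue_class(residue: str, table: ResidueClassTable | None = None) -> str:
    """Classify a single residue letter as polar/hydrophobic/glycine/other."""
    if len(residue) != 1 or not residue.isupper():
        raise ValueError(f"expected a single uppercase letter, got {residue!r}")
    table = table or ResidueClassTable()
    if residue in table.glycine:
        return "glycine"
    if residue in table.polar:
        return "polar"
    if residue in table.hydrophobic:
        return "hydrophobic"
    return "other"


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of an unmodified chain, in kDa."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos}") from None
    return total / 1000.0


def _clean(seq: str, rec_id: str) -> str:
    seq = seq.upper().replace("*", "")
    if not seq:
        raise FastaParseError(f"record {rec_id!r}: empty sequence after parsing")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read ungapped protein FASTA; uppercases and strips stop characters."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, _clean(str(rec.seq), rec.id), desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (gap character '-')."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        rows.append(AlignedRow(rec.id, str(rec.seq).upper().replace("*", ""), desc))
    if not rows:
        raise FastaParseError(f"{path}: no alignment rows")
    return Alignment(tuple(rows))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in alignment.rows
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def alignment_from_records(records: Sequence[ProteinRecord]) -> Alignment:
    """Treat equal-length ungapped records as a trivial alignment."""
    return Alignment(tuple(AlignedRow(r.id, r.sequence, r.description) for r in records))
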