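"""Degenerate residue-class motif scanning.

Mitochondrial beta-barrel proteins carry a degenerate sorting signal in
their last beta-strand ("beta-signal", canonically PxGxxHxH with P = polar,
G = glycine, H = hydrophobic, x = any residue). Because the strand itself
has no fixed sequence coordinates, hits are flagged when they fall entirely
inside a configurable C-terminal window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequence_io import ProteinRecord, ResidueClassTable

_CLASS_CODES = {"P": "polar", "G": "glycine", "H": "hydrophobic", "x": "any"}

DEFAULT_BETA_MOTIF = "PxGxxHxH"
DEFAULT_CTERM_WINDOW = 40


@dataclass(frozen=True)
class ClassPattern:
    """A positional pattern over residue classes, resolved to residue sets."""

    spec: str
    positions: tuple[frozenset[str] | None, ...]  # None = any residue

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(
            allowed is None or aa in allowed
            for aa, allowed in zip(window, self.positions)
        )


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int  # 1-based inclusive
    matched: str
    in_cterm_window: bool


def compile_pattern(spec: str, table: ResidueClassTable | None = None) -> ClassPattern:
    """Resolve a class-code string like "PxGxxHxH" against a residue table."""
    if not spec:
        raise ValueError("empty pattern spec")
    table = table or ResidueClassTable()
    sets = {"P": table.polar, "G": table.glycine, "H": table.hydrophobic}
    positions: list[frozenset[str] | None] = []
    for i, code in enumerate(spec, start=1):
        if code == "x":
            positions.append(None)
        elif code in sets:
            positions.append(frozenset(sets[code]))
        else:
            raise ValueError(f"unknown class code {code!r} at pattern position {i}")
    return ClassPattern(spec, tuple(positions))


def scan(
    record: ProteinRecord,
    pattern: ClassPattern,
    cterm_window: int = DEFAULT_CTERM_WINDOW,
) -> list[MotifHit]:
    """Test every window of pattern length; report all (overlapping) hits.

    A hit is flagged ``in_cterm_window`` when the whole match lies within the
    last ``cterm_window`` residues of the sequence.
    """
    if cterm_window < len(pattern):
        raise ValueError("cterm_window must be >= pattern length")
    seq = record.sequence
    k = len(pattern)
    hits = []
    window_start0 = max(0, len(seq) - cterm_window)  # first 0-based index inside window
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if pattern.matches(window):
            hits.append(
                MotifHit(
                    record_id=record.id,
                    start=i + 1,
                    matched=window,
                    in_cterm_window=i >= window_start0,
                )
            )
    return hits


def classify_candidates(
    records: Iterable[ProteinRecord],
    pattern: ClassPattern,
    cterm_window: int = DEFAULT_CTERM_WINDOW,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (motif_positive, motif_negative).

    Positive = at least one hit lying inside the C-terminal window.
    """
    positive, negative = [], []
    for rec in records:
        hits = scan(rec, pattern, cterm_window)
        if any(h.in_cterm_window for h in hits):
            positive.append(rec)
        else:
            negative.append(rec)
    return positive, negative


def hits_table(hits: Sequence[MotifHit]) -> list[dict]:
    return [
        {
            "record_id": h.record_id,
            "start": h.start,
            "matched": h.matched,
            "in_cterm_window": h.in_cterm_window,
        }
        for h in hits
    ]
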