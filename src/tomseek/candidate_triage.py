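"""Candidate triage: set intersections, domain architectures, Tom22 checks.

The discovery logic: proteins enriched in bait co-IPs under crosslinking
and/or native conditions are intersected with the organelle membrane
proteome; survivors are annotated with their membrane-anchor topology and
domain architecture (e.g. an N-terminal Hsp20-like chaperone domain, a few
TPR repeats and a C-terminal transmembrane anchor marks a candidate import
receptor). Short single-TMD proteins are additionally screened for the
conserved Tom22 TMD motif (tryptophan at the second motif position,
hydroxylated residues after it, serine at +4, proline in the TMD).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .profile_hmm import EvalueCalibration, ProfileHMM, domain_hits
from .sequence_io import ProteinRecord
from .tmd_predict import AnchorCall, TmdSpan, refine_span_start

HYDROXYLATED = frozenset("STY")


@dataclass(frozen=True)
class VennResult:
    set_names: tuple[str, ...]
    region_members: dict[frozenset, tuple[str, ...]]  # key: names containing region

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def members(self, *names: str) -> tuple[str, ...]:
        """Members of the exclusive region belonging to exactly these sets."""
        return self.region_members.get(frozenset(names), ())


@dataclass(frozen=True)
class DomainCall:
    label: str  # Hsp20 | TPR | TMD | other
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class DomainArchitecture:
    calls: tuple[DomainCall, ...]

    @property
    def architecture_string(self) -> str:
        if not self.calls:
            return "other"
        parts = []
        for label, group in itertools.groupby(self.calls, key=lambda c: c.label):
            k = len(list(group))
            if label == "TPR" and k > 1:
                parts.append(f"TPR({k})")
            elif label == "TPR":
                parts.append("TPR(1)")
            else:
                parts.extend([label] * k)
        return "-".join(parts)


@dataclass(frozen=True)
class Tom22FeatureReport:
    length_aa: int
    has_cterm_tmd: bool
    trp_at_motif_pos2: bool
    hydroxylated_run_after_trp: bool
    ser_at_plus4: bool
    pro_in_tmd: bool

    @property
    def passes_all(self) -> bool:
        return (
            self.has_cterm_tmd
            and self.trp_at_motif_pos2
            and self.hydroxylated_run_after_trp
            and self.ser_at_plus4
            and self.pro_in_tmd
        )


@dataclass(frozen=True)
class Candidate:
    accession: str
    tier: int  # 1 = both conditions + membrane, 2 = crosslink-only + membrane
    in_crosslink: bool
    in_native: bool
    in_membrane: bool
    anchor: str


def venn(sets: Mapping[str, Iterable[str]]) -> VennResult:
    """Exact region decomposition of 2-3 named accession sets."""
    named = {name: set(s) for name, s in sets.items()}
    if not 2 <= len(named) <= 3:
        raise ValueError("venn expects 2 or 3 named sets")
    universe = set().union(*named.values())
    regions: dict[frozenset, list[str]] = {}
    for acc in universe:
        signature = frozenset(n for n, s in named.items() if acc in s)
        regions.setdefault(signature, []).append(acc)
    return VennResult(
        set_names=tuple(named),
        region_members={k: tuple(sorted(v)) for k, v in regions.items()},
    )


def triage(
    crosslink_enriched: Iterable[str],
    native_enriched: Iterable[str],
    membrane_proteome: Iterable[str],
    anchor_calls: Mapping[str, AnchorCall] | None = None,
) -> list[Candidate]:
    """Rank candidates: both-condition support beats crosslink-only support.

    Tier 1 = enriched under both conditions and in the membrane proteome;
    tier 2 = enriched under crosslinking only and in the membrane proteome.
    """
    cross, native, membrane = (
        set(crosslink_enriched),
        set(native_enriched),
        set(membrane_proteome),
    )
    anchor_calls = anchor_calls or {}
    candidates = []
    for acc in sorted((cross & native & membrane)):
        candidates.append(
            Candidate(acc, 1, True, acc in native, True,
                      _anchor_cat(anchor_calls, acc))
        )
    for acc in sorted((cross & membrane) - native):
        candidates.append(
            Candidate(acc, 2, True, False, True, _anchor_cat(anchor_calls, acc))
        )
    return candidates


def _anchor_cat(calls: Mapping[str, AnchorCall], acc: str) -> str:
    call = calls.get(acc)
    return call.category if call is not None else "unknown"


def classify_architecture(
    record: ProteinRecord,
    hsp20_hmm: ProfileHMM,
    tpr_hmm: ProfileHMM,
    anchor_call: AnchorCall,
    hsp20_calibration: EvalueCalibration,
    tpr_calibration: EvalueCalibration,
    evalue_cutoff: float = 0.01,
) -> DomainArchitecture:
    """Greedy non-overlapping domain assignment, rendered N-to-C.

    Domain hits come from iterative best-hit excision with each domain HMM;
    the TMD call is taken from the anchor classification so both views of
    the sequence agree.
    """
    raw: list[DomainCall] = []
    for label, hmm, calib in (
        ("Hsp20", hsp20_hmm, hsp20_calibration),
        ("TPR", tpr_hmm, tpr_calibration),
    ):
        for score, (s, e) in domain_hits(
            hmm, record.sequence, calib, evalue_cutoff=evalue_cutoff
        ):
            raw.append(DomainCall(label, s, e, score))
    for span in anchor_call.spans:
        raw.append(DomainCall("TMD", span.start, span.end, span.mean_score))
    # greedy by descending score; TMD calls always kept first
    raw.sort(key=lambda c: (c.label != "TMD", -c.score))
    kept: list[DomainCall] = []
    for call in raw:
        if all(call.end < k.start or call.start > k.end for k in kept):
            kept.append(call)
    kept.sort(key=lambda c: c.start)
    return DomainArchitecture(tuple(kept))


def tom22_features(
    record: ProteinRecord,
    anchor_call: AnchorCall,
    motif_offset: int = 0,
    refine: bool = True,
) -> Tom22FeatureReport:
    """Evaluate the conserved Tom22 TMD motif on a single-TMD protein.

    The motif is anchored at the (optionally refined) TMD start plus
    ``motif_offset``: position 2 must be tryptophan, at least one
    hydroxylated residue (S/T/Y) must occur within three residues after the
    tryptophan, the residue at +4 from the tryptophan (counting W as +1)
    must be serine, and the TMD must contain a proline.
    """
    seq = record.sequence
    if anchor_call.category != "tail_anchored" or len(anchor_call.spans) != 1:
        return Tom22FeatureReport(len(seq), False, False, False, False, False)
    span = anchor_call.spans[0]
    start = refine_span_start(seq, span) if refine else span.start
    start += motif_offset
    w_pos = start + 1  # motif position 2, 1-based
    trp = w_pos <= len(seq) and seq[w_pos - 1] == "W"
    hydrox = trp and any(
        aa in HYDROXYLATED for aa in seq[w_pos : min(len(seq), w_pos + 3)]
    )
    ser = w_pos + 3 <= len(seq) and seq[w_pos + 2] == "S"
    pro = "P" in seq[start - 1 : span.end]
    return Tom22FeatureReport(
        length_aa=len(seq),
        has_cterm_tmd=True,
        trp_at_motif_pos2=trp,
        hydroxylated_run_after_trp=hydrox,
        ser_at_plus4=ser,
        pro_in_tmd=pro,
    )
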