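"""Hydropathy-based transmembrane-span prediction and anchor classification.

A sliding-window Kyte-Doolittle profile, affinely rescaled to [0, 1]
(-4.5 -> 0, +4.5 -> 1), replaces a trained topology HMM. Maximal runs of
residues above a cutoff become candidate transmembrane spans; a single span
near the C-terminus marks a tail-anchored protein, a single span near the
N-terminus a signal-anchored one.

The "relaxed" preset (cutoff 0.7 instead of the default 0.8) plays the role
of a lowered posterior-probability threshold in trained predictors; the two
scales are not numerically interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import ProteinRecord

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_KD_MIN, _KD_MAX = -4.5, 4.5

DEFAULT_WINDOW = 19
DEFAULT_CUTOFF = 0.8
RELAXED_CUTOFF = 0.7
DEFAULT_MIN_LEN = 15
DEFAULT_MERGE_GAP = 3


@dataclass(frozen=True)
class TmdSpan:
    start: int  # 1-based inclusive
    end: int
    mean_score: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("span end before start")
        if not 0.0 <= self.mean_score <= 1.0:
            raise ValueError("mean_score outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnchorCall:
    category: str  # tail_anchored | signal_anchored | polytopic | none
    spans: tuple[TmdSpan, ...]


def _kd_values(sequence: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence])


def hydropathy_profile(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-residue normalised hydropathy in [0, 1].

    Sliding-window mean of Kyte-Doolittle values; near the termini the
    window shrinks to what is available. Unknown residues count as 0.0
    (scale midpoint).
    """
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    if len(sequence) < 7:
        raise ValueError("sequence shorter than 7 residues")
    vals = _kd_values(sequence)
    half = window // 2
    n = len(vals)
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (cum[hi] - cum[lo]) / (hi - lo)
    return np.clip((out - _KD_MIN) / (_KD_MAX - _KD_MIN), 0.0, 1.0)


def predict_tmds(
    sequence: str,
    cutoff: float = DEFAULT_CUTOFF,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    window: int = DEFAULT_WINDOW,
) -> list[TmdSpan]:
    """Maximal above-cutoff runs, nearby runs merged, short runs dropped."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if len(sequence) < 7:
        return []
    profile = hydropathy_profile(sequence, window)
    above = profile >= cutoff
    runs: list[list[int]] = []  # [start0, end0] inclusive
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    spans = []
    for s, e in runs:
        if e - s + 1 >= min_len:
            spans.append(TmdSpan(s + 1, e + 1, float(profile[s : e + 1].mean())))
    return spans


def classify_anchor(
    record: ProteinRecord,
    spans: list[TmdSpan] | None = None,
    cterm_window: int = 35,
    nterm_window: int = 35,
    **predict_kwargs,
) -> AnchorCall:
    """Classify membrane-anchor topology from predicted spans.

    One span ending inside the last ``cterm_window`` residues -> tail
    anchored (checked first: tail anchors are the discovery focus); one span
    starting inside the first ``nterm_window`` -> signal anchored; two or
    more spans -> polytopic; otherwise none.
    """
    if spans is None:
        spans = predict_tmds(record.sequence, **predict_kwargs)
    spans_t = tuple(spans)
    n = len(record.sequence)
    if not spans_t:
        return AnchorCall("none", spans_t)
    if len(spans_t) >= 2:
        return AnchorCall("polytopic", spans_t)
    span = spans_t[0]
    if span.end >= n - cterm_window + 1:
        return AnchorCall("tail_anchored", spans_t)
    if span.start <= nterm_window:
        return AnchorCall("signal_anchored", spans_t)
    return AnchorCall("none", spans_t)


def refine_span_start(sequence: str, span: TmdSpan, kd_floor: float = -2.0) -> int:
    """Snap a span start leftwards to the start of its hydrophobic run.

    Window smoothing shifts span edges by up to half a window; for
    positional motif checks (e.g. the Tom22 TMD motif) the anchor is the
    first residue of the contiguous run with Kyte-Doolittle value >=
    ``kd_floor`` that contains the span. The default floor keeps W/S/T/P
    inside the run but breaks at strongly polar/charged residues.
    """
    vals = _kd_values(sequence)
    i = span.start - 1
    while i > 0 and vals[i - 1] >= kd_floor:
        i -= 1
    return i + 1  # 1-based
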