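"""Profile hidden Markov models: build from an alignment, score, calibrate.

A compact re-implementation of the classic profile-HMM homology search:
match/insert/delete states, local (Smith-Waterman-like) alignment mode with
uniform entry over match states, log-space dynamic programming, and explicit
E-value calibration by fitting a Gumbel distribution to the forward scores
of i.i.d. background decoys. Scores are reported in bits (log2-odds against
the background null model).

Model semantics (shared by the dynamic programming here and by the
exhaustive path-enumeration oracle used in the tests): a local alignment
enters at any match state j0 with probability 1/n_match, moves through
match (M), insert (I) and delete (D) states under the model's transition
probabilities, and may exit after any match state at no cost. Match and
insert states emit residues scored as log2(emission/background); delete
states are silent. The Viterbi score is the best single path; the forward
score is the log2-sum over all paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .sequence_io import AMINO_ACIDS, Alignment, ProteinRecord

LN2 = math.log(2.0)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Constant state-transition probabilities (HMMER-like magnitudes). The
# builder emits these for every state; estimating them from the alignment
# adds nothing at desk scale.
DEFAULT_TRANSITIONS = {
    "MM": 0.90, "MI": 0.05, "MD": 0.05,
    "IM": 0.60, "II": 0.40,
    "DM": 0.70, "DD": 0.30,
}


@dataclass(frozen=True)
class ProfileHMM:
    """A local-mode profile HMM over the 20-letter amino-acid alphabet."""

    n_match: int
    match_emissions: np.ndarray  # (n_match, 20), rows sum to 1
    insert_emissions: np.ndarray  # (n_match, 20), rows sum to 1
    transitions: np.ndarray  # (n_match, 7): MM MI MD IM II DM DD
    background: np.ndarray  # (20,), sums to 1

    def __post_init__(self):
        if self.n_match < 1:
            raise ValueError("n_match must be >= 1")
        for name, rows, groups in (
            ("match_emissions", self.match_emissions, [slice(None)]),
            ("insert_emissions", self.insert_emissions, [slice(None)]),
            ("transitions", self.transitions, [slice(0, 3), slice(3, 5), slice(5, 7)]),
        ):
            for g in groups:
                sums = rows[:, g].sum(axis=1)
                if not np.allclose(sums, 1.0, atol=1e-9):
                    raise ValueError(f"{name}: probability rows do not sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background does not sum to 1")


@dataclass(frozen=True)
class HmmHit:
    record_id: str
    bit_score: float
    e_value: float
    span: tuple[int, int]  # 1-based inclusive region of the sequence


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel null fit to decoy scores: E(s) = N exp(-lambda (s - mu)).

    Calibrated on Viterbi bit scores by default: optimal-alignment scores of
    i.i.d. sequences follow a Gumbel law, whereas forward (sum) scores have
    a visibly heavier right tail that a Gumbel fit underestimates.
    """

    mu: float
    lambda_: float
    n_decoys: int
    decoy_length: int
    seed: int
    score_type: str = "viterbi"

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")

    def evalue(self, bit_score: float, n_db: int) -> float:
        e = n_db * math.exp(-self.lambda_ * (bit_score - self.mu))
        return float(min(max(e, 0.0), n_db))


def build_hmm(
    alignment: Alignment,
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
) -> ProfileHMM:
    """Build a profile HMM from a gapped alignment.

    Columns whose non-gap fraction is at least ``occupancy_threshold`` become
    match states. Emissions are observed counts mixed with
    ``pseudocount_weight`` times the background; the background is the
    residue frequency over the whole alignment (uniform if none).
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be non-negative")

    n_rows = alignment.n_rows
    counts_total = np.zeros(20)
    match_cols = []
    col_counts = []
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        counts = np.zeros(20)
        for aa in col:
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
        counts_total += counts
        occupancy = sum(1 for aa in col if aa != "-") / n_rows
        if occupancy >= occupancy_threshold:
            match_cols.append(j)
            col_counts.append(counts)
    if not match_cols:
        raise ValueError("no alignment column meets the occupancy threshold")

    if counts_total.sum() > 0:
        background = counts_total / counts_total.sum()
    else:  # pragma: no cover - all-gap alignments are rejected upstream
        background = np.full(20, 1 / 20)
    # zero-frequency residues would make log-odds undefined; give them a floor
    background = (background + 1e-4) / (background + 1e-4).sum()

    n_match = len(match_cols)
    match_em = np.empty((n_match, 20))
    for k, counts in enumerate(col_counts):
        mixed = counts + pseudocount_weight * background
        if pseudocount_weight == 0 and counts.sum() == 0:
            mixed = background.copy()
        match_em[k] = mixed / mixed.sum()
    insert_em = np.tile(background, (n_match, 1))
    trans = np.tile(
        [DEFAULT_TRANSITIONS[k] for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")],
        (n_match, 1),
    )
    return ProfileHMM(n_match, match_em, insert_em, trans, background)


def encode(sequence: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown letters (e.g. X) -> -1."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)


def _log_odds(hmm: ProfileHMM) -> tuple[np.ndarray, np.ndarray]:
    """(n_match, 21) log2-odds tables for match/insert; column 20 = unknown (0)."""
    lm = np.zeros((hmm.n_match, 21))
    li = np.zeros((hmm.n_match, 21))
    with np.errstate(divide="ignore"):
        lm[:, :20] = np.log2(hmm.match_emissions) - np.log2(hmm.background)
        li[:, :20] = np.log2(hmm.insert_emissions) - np.log2(hmm.background)
    return lm, li


def _scalar_transitions(hmm: ProfileHMM) -> dict[str, float]:
    keys = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
    if np.ptp(hmm.transitions, axis=0).max() > 1e-12:
        raise NotImplementedError("scoring requires state-constant transitions")
    row = hmm.transitions[0]
    return {k: math.log2(row[i]) for i, k in enumerate(keys)}


def _viterbi_matrices(hmm: ProfileHMM, sequence: str):
    """Row-vectorised local Viterbi; returns (VM, VI, VD) of shape (L, n)."""
    x = encode(sequence)
    L, n = len(x), hmm.n_match
    lm, li = _log_odds(hmm)
    t = _scalar_transitions(hmm)
    entry = -math.log2(n)
    neg = -np.inf
    VM = np.full((L, n), neg)
    VI = np.full((L, n), neg)
    VD = np.full((L, n), neg)
    ar = np.arange(n)
    for i in range(L):
        lmx, lix = lm[:, x[i]], li[:, x[i]]
        if i == 0:
            VM[0] = lmx + entry
            # delete chain within row 0
            g = VM[0] - ar * t["DD"]
            cm = np.maximum.accumulate(g)
            VD[0, 1:] = cm[:-1] + t["MD"] + (ar[1:] - 1) * t["DD"]
            continue
        pm, pi, pd = VM[i - 1], VI[i - 1], VD[i - 1]
        from_m = np.concatenate(([neg], pm[:-1] + t["MM"]))
        from_i = np.concatenate(([neg], pi[:-1] + t["IM"]))
        from_d = np.concatenate(([neg], pd[:-1] + t["DM"]))
        VM[i] = lmx + np.maximum.reduce([np.full(n, entry), from_m, from_i, from_d])
        VI[i] = lix + np.maximum(pm + t["MI"], pi + t["II"])
        g = VM[i] - ar * t["DD"]
        cm = np.maximum.accumulate(g)
        VD[i, 1:] = cm[:-1] + t["MD"] + (ar[1:] - 1) * t["DD"]
    return VM, VI, VD


def viterbi_score(hmm: ProfileHMM, sequence: str) -> float:
    """Best local alignment score in bits."""
    if not sequence:
        raise ValueError("empty sequence")
    VM, _, _ = _viterbi_matrices(hmm, sequence)
    return float(VM.max())


def forward_score(hmm: ProfileHMM, sequence: str) -> float:
    """Total local alignment score (log2-sum over all paths) in bits."""
    if not sequence:
        raise ValueError("empty sequence")
    x = encode(sequence)
    L, n = len(x), hmm.n_match
    lm, li = _log_odds(hmm)
    t = {k: v * LN2 for k, v in _scalar_transitions(hmm).items()}  # nats
    lm, li = lm * LN2, li * LN2
    entry = -math.log(n)
    neg = -np.inf
    ar = np.arange(n)
    FM = np.full(n, neg)
    FI = np.full(n, neg)
    FD = np.full(n, neg)
    total = neg
    for i in range(L):
        lmx, lix = lm[:, x[i]], li[:, x[i]]
        if i == 0:
            FM = lmx + entry
        else:
            from_m = np.concatenate(([neg], FM[:-1] + t["MM"]))
            from_i = np.concatenate(([neg], FI[:-1] + t["IM"]))
            from_d = np.concatenate(([neg], FD[:-1] + t["DM"]))
            newM = lmx + np.logaddexp(
                np.logaddexp(entry, from_m), np.logaddexp(from_i, from_d)
            )
            FI = lix + np.logaddexp(FM + t["MI"], FI + t["II"])
            FM = newM
        g = FM - ar * t["DD"]
        acc = np.logaddexp.accumulate(g)
        FD = np.full(n, neg)
        if n > 1:
            FD[1:] = acc[:-1] + t["MD"] + (ar[1:] - 1) * t["DD"]
        total = np.logaddexp(total, float(np.logaddexp.reduce(FM)))
    return float(total / LN2)


def viterbi_alignment(hmm: ProfileHMM, sequence: str) -> tuple[float, tuple[int, int]]:
    """Viterbi score plus the 1-based sequence span of the best path."""
    VM, VI, VD = _viterbi_matrices(hmm, sequence)
    t = _scalar_transitions(hmm)
    lm, li = _log_odds(hmm)
    x = encode(sequence)
    entry = -math.log2(hmm.n_match)
    i, j = np.unravel_index(int(np.argmax(VM)), VM.shape)
    score = float(VM[i, j])
    end_i = int(i)
    tol = 1e-7
    state = "M"
    while True:
        if state == "M":
            base = VM[i, j] - lm[j, x[i]]
            if abs(base - entry) <= tol or (i == 0):
                break
            if j > 0 and abs(base - (VM[i - 1, j - 1] + t["MM"])) <= tol:
                i, j, state = i - 1, j - 1, "M"
            elif j > 0 and abs(base - (VI[i - 1, j - 1] + t["IM"])) <= tol:
                i, j, state = i - 1, j - 1, "I"
            elif j > 0 and abs(base - (VD[i - 1, j - 1] + t["DM"])) <= tol:
                i, j, state = i - 1, j - 1, "D"
            else:  # numerically closest to entry
                break
        elif state == "I":
            base = VI[i, j] - li[j, x[i]]
            if abs(base - (VM[i - 1, j] + t["MI"])) <= tol:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
        else:  # D
            if j > 0 and abs(VD[i, j] - (VM[i, j - 1] + t["MD"])) <= tol:
                j, state = j - 1, "M"
            else:
                j, state = j - 1, "D"
    return score, (int(i) + 1, end_i + 1)


def calibrate_evalue(
    hmm: ProfileHMM,
    n_decoys: int = 200,
    decoy_length: int = 150,
    seed: int = 0,
    score_type: str = "viterbi",
) -> EvalueCalibration:
    """Fit a Gumbel null (maximum likelihood) to i.i.d. background decoys."""
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys for a stable fit")
    score_fn = {"viterbi": viterbi_score, "forward": forward_score}[score_type]
    rng = np.random.default_rng(seed)
    scores = np.array(
        [
            score_fn(hmm, decoy_sequence(hmm.background, decoy_length, rng))
            for _ in range(n_decoys)
        ]
    )
    if scores.std() < 1e-9:
        raise ValueError("degenerate decoy scores (zero variance)")
    mu, scale = stats.gumbel_r.fit(scores)
    return EvalueCalibration(
        mu=float(mu),
        lambda_=float(1.0 / scale),
        n_decoys=n_decoys,
        decoy_length=decoy_length,
        seed=seed,
        score_type=score_type,
    )


def decoy_sequence(background: np.ndarray, length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(AMINO_ACIDS[i] for i in idx)


def search_proteome(
    hmm: ProfileHMM,
    records: Sequence[ProteinRecord],
    calibration: EvalueCalibration,
    compute_spans: bool = True,
) -> list[HmmHit]:
    """Score every record; rank by bit score descending, ties by id.

    Scores match the calibration's score type so E-values stay meaningful.
    """
    n_db = len(records)
    score_fn = {"viterbi": viterbi_score, "forward": forward_score}[
        calibration.score_type
    ]
    hits = []
    for rec in records:
        if compute_spans and calibration.score_type == "viterbi":
            bit, span = viterbi_alignment(hmm, rec.sequence)
        else:
            bit = score_fn(hmm, rec.sequence)
            span = (1, len(rec.sequence))
            if compute_spans:
                _, span = viterbi_alignment(hmm, rec.sequence)
        hits.append(
            HmmHit(rec.id, bit, calibration.evalue(bit, n_db), span)
        )
    hits.sort(key=lambda h: (-h.bit_score, h.record_id))
    return hits


def domain_hits(
    hmm: ProfileHMM,
    sequence: str,
    calibration: EvalueCalibration,
    evalue_cutoff: float = 0.01,
    n_db: int = 1,
    max_hits: int = 10,
    min_bits: float = 0.0,
) -> list[tuple[float, tuple[int, int]]]:
    """Greedy non-overlapping domain calls by repeated best-hit excision.

    Finds the best local Viterbi alignment; if it clears the E-value cutoff,
    records its span and recurses on the flanking segments. Used for
    multi-copy domains such as TPR repeats.
    """
    results: list[tuple[float, tuple[int, int]]] = []

    def _recurse(seq: str, offset: int) -> None:
        if len(results) >= max_hits or len(seq) < 3:
            return
        score, (s, e) = viterbi_alignment(hmm, seq)
        if score <= min_bits or calibration.evalue(score, n_db) > evalue_cutoff:
            return
        results.append((score, (s + offset, e + offset)))
        _recurse(seq[: s - 1], offset)
        _recurse(seq[e:], offset + e)

    _recurse(sequence, 0)
    results.sort(key=lambda r: r[1][0])
    return results
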