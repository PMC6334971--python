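import itertools
import math

import numpy as np
import pytest

from tomseek import profile_hmm as ph
from tomseek import sequence_io as sio
from tomseek import synthetic_data as sd

AA = sio.AMINO_ACIDS


def tiny_hmm(n_match: int, peaks: list[str], seed: int = 0) -> ph.ProfileHMM:
    """Small hand-made model: each match state peaked on one residue."""
    rng = np.random.default_rng(seed)
    bg = np.full(20, 1 / 20)
    match = np.empty((n_match, 20))
    for j, aa in enumerate(peaks):
        row = rng.uniform(0.01, 0.05, 20)
        row[AA.index(aa)] = 1.0
        match[j] = row / row.sum()
    trans = np.tile(
        [ph.DEFAULT_TRANSITIONS[k] for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")],
        (n_match, 1),
    )
    return ph.ProfileHMM(n_match, match, np.tile(bg, (n_match, 1)), trans, bg)


def enumerate_path_scores(hmm: ph.ProfileHMM, seq: str) -> list[float]:
    """Exhaustive enumeration of every local state path (log2 scores).

    Mirrors the declared model semantics only - not the DP recurrences:
    enter at any match state/position, walk M/I/D transitions, stop after
    any match state.
    """
    x = [AA.index(a) for a in seq]
    n, L = hmm.n_match, len(seq)
    bg = hmm.background
    t = {k: math.log2(v) for k, v in ph.DEFAULT_TRANSITIONS.items()}
    lm = np.log2(hmm.match_emissions) - np.log2(bg)
    li = np.log2(hmm.insert_emissions) - np.log2(bg)
    entry = -math.log2(n)
    scores: list[float] = []

    def walk(state: str, j: int, i: int, acc: float) -> None:
        # i = index of the next residue to consume (0-based)
        if state == "M":
            scores.append(acc)  # may stop after any match state
            if j + 1 < n and i < L:
                walk("M", j + 1, i + 1, acc + t["MM"] + lm[j + 1, x[i]])
            if i < L:
                walk("I", j, i + 1, acc + t["MI"] + li[j, x[i]])
            if j + 1 < n:
                walk("D", j + 1, i, acc + t["MD"])
        elif state == "I":
            if j + 1 < n and i < L:
                walk("M", j + 1, i + 1, acc + t["IM"] + lm[j + 1, x[i]])
            if i < L:
                walk("I", j, i + 1, acc + t["II"] + li[j, x[i]])
        else:  # D
            if j + 1 < n and i < L:
                walk("M", j + 1, i + 1, acc + t["DM"] + lm[j + 1, x[i]])
            if j + 1 < n:
                walk("D", j + 1, i, acc + t["DD"])

    for i0 in range(L):
        for j0 in range(n):
            walk("M", j0, i0 + 1, entry + lm[j0, x[i0]])
    return scores


class TestBuild:
    def test_single_sequence_peaked_match_states(self):
        aln = sio.Alignment((sio.AlignedRow("a", "ACDEFGHIKL"),))
        hmm = ph.build_hmm(aln, pseudocount_weight=0.1)
        assert hmm.n_match == 10
        for j, aa in enumerate("ACDEFGHIKL"):
            assert hmm.match_emissions[j].argmax() == AA.index(aa)

    def test_mostly_gapped_column_excluded(self):
        rows = tuple(
            sio.AlignedRow(f"r{i}", s)
            for i, s in enumerate(["A-CD", "A-CD", "A-CD", "AKCD"])
        )
        hmm = ph.build_hmm(sio.Alignment(rows), occupancy_threshold=0.5)
        assert hmm.n_match == 3  # column 2 is 75% gaps

    def test_emission_rows_normalised(self, barrel_hmm):
        assert np.allclose(barrel_hmm.match_emissions.sum(1), 1.0, atol=1e-9)
        assert np.allclose(barrel_hmm.insert_emissions.sum(1), 1.0, atol=1e-9)
        tr = barrel_hmm.transitions
        assert np.allclose(tr[:, :3].sum(1), 1.0, atol=1e-9)
        assert np.allclose(tr[:, 3:5].sum(1), 1.0, atol=1e-9)
        assert np.allclose(tr[:, 5:].sum(1), 1.0, atol=1e-9)

    def test_no_qualifying_column_is_error(self):
        rows = (sio.AlignedRow("a", "A-"), sio.AlignedRow("b", "-A"))
        with pytest.raises(ValueError):
            ph.build_hmm(sio.Alignment(rows), occupancy_threshold=0.9)


class TestScoring:
    def test_one_state_one_residue_closed_form(self):
        hmm = tiny_hmm(1, ["W"])
        expected = math.log2(hmm.match_emissions[0, AA.index("W")] / (1 / 20))
        assert ph.viterbi_score(hmm, "W") == pytest.approx(expected, abs=1e-9)
        # forward over a single path equals the same closed form
        assert ph.forward_score(hmm, "W") == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("n_match", [1, 2, 3])
    @pytest.mark.parametrize("seq", ["W", "AW", "WKD", "AWKV"])
    def test_dp_equals_exhaustive_enumeration(self, n_match, seq):
        hmm = tiny_hmm(n_match, list("WKV")[:n_match], seed=n_match)
        scores = enumerate_path_scores(hmm, seq)
        assert ph.viterbi_score(hmm, seq) == pytest.approx(max(scores), abs=1e-7)
        forward = math.log2(sum(2.0**s for s in scores))
        assert ph.forward_score(hmm, seq) == pytest.approx(forward, abs=1e-7)

    def test_forward_at_least_viterbi_random_models(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(1, 6))
            peaks = [AA[i] for i in rng.integers(0, 20, n)]
            hmm = tiny_hmm(n, peaks, seed=trial)
            seq = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 30)))
            assert ph.forward_score(hmm, seq) >= ph.viterbi_score(hmm, seq) - 1e-9

    def test_training_sequence_beats_its_shuffles(self, barrel_hmm, barrel_family):
        rng = np.random.default_rng(12)
        seq = barrel_family[0].sequence
        ref = ph.forward_score(barrel_hmm, seq)
        wins = 0
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(seq)))
            wins += ref > ph.forward_score(barrel_hmm, shuffled)
        assert wins >= 95

    def test_viterbi_alignment_span_covers_planted_region(self, barrel_hmm):
        rng = np.random.default_rng(4)
        flank = "".join(AA[i] for i in rng.integers(0, 20, 30))
        seq = flank + sd.BARREL_TEMPLATE + flank
        score, (s, e) = ph.viterbi_alignment(barrel_hmm, seq)
        assert score > 100
        assert s >= 25 and e <= len(seq) - 25  # span sits in the barrel region
        assert e - s + 1 > 80


class TestCalibration:
    def test_same_seed_identical_fit(self, barrel_hmm):
        a = ph.calibrate_evalue(barrel_hmm, 60, 100, seed=9)
        b = ph.calibrate_evalue(barrel_hmm, 60, 100, seed=9)
        assert (a.mu, a.lambda_) == (b.mu, b.lambda_)
        assert a.lambda_ > 0

    def test_self_consistency_of_evalues(self, barrel_hmm):
        calib = ph.calibrate_evalue(barrel_hmm, 200, 100, seed=2)
        rng = np.random.default_rng(2)
        scores = [
            ph.viterbi_score(
                barrel_hmm, ph.decoy_sequence(barrel_hmm.background, 100, rng)
            )
            for _ in range(200)
        ]
        n_signif = sum(calib.evalue(s, 200) <= 1.0 for s in scores)
        assert n_signif <= 4  # within Poisson error of the expected 1

    def test_too_few_decoys_rejected(self, barrel_hmm):
        with pytest.raises(ValueError):
            ph.calibrate_evalue(barrel_hmm, 10, 100, seed=0)


class TestSearch:
    def test_empty_proteome(self, barrel_hmm, barrel_calibration):
        assert ph.search_proteome(barrel_hmm, [], barrel_calibration) == []

    def test_ranking_invariant_under_record_order(
        self, barrel_hmm, barrel_calibration
    ):
        spec = sd.ProteomeSpec(
            families=(sd.FamilySpec("P", "barrel", 2, 0.1),), n_decoys=10
        )
        records, _ = sd.gen_proteome(spec, 21)
        fwd = ph.search_proteome(
            barrel_hmm, records, barrel_calibration, compute_spans=False
        )
        rev = ph.search_proteome(
            barrel_hmm, records[::-1], barrel_calibration, compute_spans=False
        )
        assert [h.record_id for h in fwd] == [h.record_id for h in rev]

    def test_planted_member_ranks_first_over_seeds(
        self, barrel_hmm, barrel_calibration
    ):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = sd.ProteomeSpec(
                families=(sd.FamilySpec("PLANT", "barrel", 1, 0.10),),
                n_decoys=100,
                decoy_length=120,
            )
            records, _ = sd.gen_proteome(spec, seed)
            hits = ph.search_proteome(
                barrel_hmm, records, barrel_calibration, compute_spans=False
            )
            wins += hits[0].record_id.startswith("PLANT")
        assert wins == n_seeds

    def test_agrees_with_hmmer_top_hit(self, barrel_family, barrel_calibration):
        """Independent cross-check: pyhmmer ranks the same planted member first."""
        pyhmmer = pytest.importorskip("pyhmmer")
        spec = sd.ProteomeSpec(
            families=(sd.FamilySpec("PLANT", "barrel", 1, 0.10),), n_decoys=60
        )
        records, _ = sd.gen_proteome(spec, 77)
        abc = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(
            name=b"fam",
            sequences=[
                pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.sequence)
                for r in barrel_family
            ],
        ).digitize(abc)
        builder = pyhmmer.plan7.Builder(abc)
        hmm, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(abc))
        seqs = [
            pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.sequence)
            .digitize(abc)
            for r in records
        ]
        top = list(pyhmmer.hmmsearch([hmm], seqs))[0]
        best_hmmer = max(top, key=lambda h: h.score).name
        if isinstance(best_hmmer, bytes):
            best_hmmer = best_hmmer.decode()
        hmm_ours = ph.build_hmm(sio.alignment_from_records(barrel_family))
        ours = ph.search_proteome(
            hmm_ours, records, barrel_calibration, compute_spans=False
        )
        assert ours[0].record_id == best_hmmer
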