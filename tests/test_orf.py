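import numpy as np
import pytest
from scipy import stats as sps

from protannot import translate
from protannot.orf import (
    MarkovCodingModel,
    OpenReadingFrame,
    enumerate_orfs,
    refine_start,
    score_orf,
    select_orfs,
    train_model,
)
from protannot.synthetic import _CODON_P, _CODONS, _random_dna, random_frame_markov, sample_frame_markov

from conftest import make_pt


def _stop_free_codons(rng, n):
    idx = rng.choice(len(_CODONS), size=n, p=_CODON_P)
    return "".join(_CODONS[i] for i in idx)


class TestEnumerateOrfs:
    def test_single_complete_orf_of_101_aa(self):
        rng = np.random.default_rng(0)
        seq = "ATG" + _stop_free_codons(rng, 100) + "TAA"
        orfs = [o for o in enumerate_orfs(seq, min_len_aa=100) if o.completeness == "complete"]
        assert len(orfs) == 1
        assert len(orfs[0].peptide) == 101
        assert orfs[0].t_start == 1 and orfs[0].t_end == len(seq)

    def test_below_length_gate_yields_nothing(self):
        assert enumerate_orfs("ATGTAA", min_len_aa=100) == []

    def test_no_atg_no_stop_gives_internal_orf(self):
        rng = np.random.default_rng(1)
        # frame 1 of this sequence has neither ATG nor stop
        seq = "GGC" * 120
        orfs = enumerate_orfs(seq, min_len_aa=100, allow_partial=True)
        assert any(o.completeness == "internal" for o in orfs)

    def test_partials_suppressed_when_disallowed(self):
        rng = np.random.default_rng(2)
        body = _stop_free_codons(rng, 150)
        orfs = enumerate_orfs(body, min_len_aa=100, allow_partial=False)
        assert all(o.completeness == "complete" for o in orfs)

    def test_five_prime_partial_at_transcript_edge(self):
        rng = np.random.default_rng(3)
        body = _stop_free_codons(rng, 120).replace("ATG", "CCC")
        seq = body + "TAA" + "T"
        orfs = enumerate_orfs(seq, min_len_aa=50, allow_partial=True)
        assert any(o.completeness == "5prime_partial" and o.t_start == 1 for o in orfs)

    def test_no_enumerated_orf_has_internal_stop(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = _random_dna(rng, int(rng.integers(300, 1200)), 0.5)
            for o in enumerate_orfs(seq, min_len_aa=20):
                assert not translate(o.nt).internal_stop
                assert (o.t_end - o.t_start + 1) % 3 == 0


class TestMarkovCodingModel:
    def test_zero_information_model_scores_zero(self):
        m = MarkovCodingModel.zero()
        assert score_orf(m, "ATG" + "GCC" * 50 + "TAA") == 0.0

    def test_identical_coding_and_background_gives_near_zero_scores(self):
        rng = np.random.default_rng(5)
        seqs = [_random_dna(rng, 600, 0.5) for _ in range(40)]
        m = MarkovCodingModel.train(seqs, seqs)
        s = m.score(seqs[0][:300])
        assert abs(s) / 300 < 0.02  # same data on both sides: log-odds ~ 0

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(6)
        coding = ["ATG" + _stop_free_codons(np.random.default_rng(i), 120) + "TAA" for i in range(30)]
        bg = [_random_dna(rng, 500, 0.45) for _ in range(30)]
        m1 = MarkovCodingModel.train(coding, bg)
        m2 = MarkovCodingModel.train(coding, bg)
        for a, b in zip(m1.log_odds, m2.log_odds):
            np.testing.assert_array_equal(a, b)

    def test_score_additive_over_in_frame_concatenation(self):
        rng = np.random.default_rng(7)
        coding = ["ATG" + _stop_free_codons(np.random.default_rng(100 + i), 150) + "TGA" for i in range(30)]
        bg = [_random_dna(rng, 600, 0.45) for _ in range(30)]
        m = MarkovCodingModel.train(coding, bg)
        s1 = _stop_free_codons(rng, 40)
        s2 = _stop_free_codons(rng, 33)
        whole = m.score(s1 + s2)
        parts = m.score(s1) + m.score(s2, prev_context=s1, frame_offset=len(s1) % 3)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            score_orf(MarkovCodingModel.zero(), "ATGT")

    def test_coding_samples_outscore_background_samples(self):
        """Sequences simulated from the coding table must score higher than
        background-simulated ones (n=200 pairs, 300 nt, sign test p<0.01)."""
        rng = np.random.default_rng(8)
        coding_train = ["ATG" + _stop_free_codons(np.random.default_rng(200 + i), 200) + "TAA"
                        for i in range(60)]
        bg_train = [_random_dna(np.random.default_rng(400 + i), 900, 0.42) for i in range(60)]
        m = MarkovCodingModel.train(coding_train, bg_train)
        diffs = []
        for i in range(200):
            c = _stop_free_codons(np.random.default_rng(1000 + i), 100)
            b = _random_dna(np.random.default_rng(2000 + i), 300, 0.42)
            diffs.append(m.score(c) - m.score(b))
        n_pos = sum(d > 0 for d in diffs)
        assert np.mean(diffs) > 0
        assert sps.binomtest(n_pos, len(diffs), 0.5, alternative="greater").pvalue < 0.01


class TestTrainModel:
    def test_duplicate_longest_orfs_deduplicated(self):
        rng = np.random.default_rng(9)
        orf = "ATG" + _stop_free_codons(rng, 150) + "TAA"
        pts = [make_pt(orf, pt_id=f"p{i}") for i in range(3)]
        m = train_model(pts, min_training=1)
        assert m.n_training == 1

    def test_fallback_to_zero_model_below_minimum(self, caplog):
        rng = np.random.default_rng(10)
        pts = [make_pt("ATG" + _stop_free_codons(rng, 120) + "TAA")]
        with caplog.at_level("WARNING"):
            m = train_model(pts, min_training=50)
        assert m.is_zero
        assert "zero-information" in caplog.text


class TestRefineStart:
    def test_trims_noncoding_extension_to_true_start(self):
        rng = np.random.default_rng(11)
        coding_train = ["ATG" + _stop_free_codons(np.random.default_rng(300 + i), 200) + "TAA"
                        for i in range(60)]
        bg_train = [_random_dna(np.random.default_rng(500 + i), 900, 0.42) for i in range(60)]
        m = MarkovCodingModel.train(coding_train, bg_train)
        true_orf = "ATG" + _stop_free_codons(rng, 150) + "TAA"
        # chance upstream in-frame ATG followed by iid background, no stop
        codons = []
        while len(codons) < 60:
            c = _random_dna(rng, 3, 0.42)
            if c not in ("TAA", "TAG", "TGA", "ATG"):
                codons.append(c)
        prefix = "ATG" + "".join(codons)
        seq = prefix + true_orf
        orf = OpenReadingFrame(
            pt_id="p", t_start=1, t_end=len(seq), completeness="complete",
            peptide=translate(seq).peptide[:-1], nt=seq,
        )
        refined = refine_start(m, orf, min_len_aa=100)
        assert refined.t_start == len(prefix) + 1
        assert refined.nt == true_orf

    def test_partial_orfs_returned_unchanged(self):
        m = MarkovCodingModel.zero()
        orf = OpenReadingFrame("p", 1, 300, "5prime_partial", "X" * 99, "ACG" * 100)
        assert refine_start(m, orf) is orf


class TestSelectOrfs:
    def _orf(self, start, end, score, completeness="complete"):
        n = end - start + 1
        return OpenReadingFrame("p", start, end, completeness,
                                "M" * (n // 3 - 1), "ATG" * (n // 3), score=score)

    def test_non_overlapping_passers_all_retained(self):
        a, b = self._orf(1, 300, 40), self._orf(401, 900, 25)
        assert len(select_orfs([a, b], min_score=0, min_len_aa=50)) == 2

    def test_overlap_resolved_by_score(self):
        a, b = self._orf(1, 300, 40), self._orf(200, 700, 25)
        kept = select_orfs([a, b], min_score=0, min_len_aa=50)
        assert kept == [a]

    def test_equal_scores_resolved_by_length(self):
        long = self._orf(1, 600, 30)
        short = self._orf(400, 849, 30)
        kept = select_orfs([long, short], min_score=0, min_len_aa=50)
        assert kept == [long]

    def test_selection_invariant_under_input_permutation(self):
        orfs = [self._orf(1, 300, 10), self._orf(200, 700, 12), self._orf(800, 1100, 5)]
        base = select_orfs(orfs, 0, 50)
        perm = select_orfs(orfs[::-1], 0, 50)
        assert [(o.t_start, o.t_end) for o in base] == [(o.t_start, o.t_end) for o in perm]

    def test_output_pairwise_non_overlapping(self):
        rng = np.random.default_rng(12)
        orfs = []
        for _ in range(30):
            s = int(rng.integers(1, 3000))
            ln = int(rng.integers(50, 200)) * 3
            orfs.append(self._orf(s, s + ln - 1, float(rng.normal(10, 5))))
        kept = select_orfs(orfs, min_score=-100, min_len_aa=10)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not a.overlaps(b)
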