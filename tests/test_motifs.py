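"""Motif parsing, exact p-value calibration, scanning, and rank-sum tests."""

import io
from itertools import product
from math import comb

import numpy as np
import pytest

from promsig.motifs import (
    BackgroundModel,
    MotifScanner,
    PWM,
    count_hits,
    log_odds,
    motif_gc,
    motif_overrepresentation,
    parse_motifs,
    permute_pwm,
    scan,
    score_pvalue_distribution,
)
from tests.conftest import random_pwm

JASPAR_TEXT = """>MA0001.1 toy
A [ 10  0  5 ]
C [  0 10  5 ]
G [  0  0  0 ]
T [  0  0  0 ]
"""

MEME_TEXT = """MEME version 4

ALPHABET= ACGT

strands: + -

MOTIF toy1
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
0.970000 0.010000 0.010000 0.010000
0.010000 0.970000 0.010000 0.010000
"""


class TestParsing:
    def test_jaspar_counts_get_quarter_pseudocount(self):
        pwms = parse_motifs(io.StringIO(JASPAR_TEXT), "jaspar")
        assert len(pwms) == 1
        # column with counts (10,0,0,0) -> (10.25, .25, .25, .25)/11
        np.testing.assert_allclose(
            pwms[0].probs[0], np.array([10.25, 0.25, 0.25, 0.25]) / 11.0
        )

    def test_meme_probabilities_kept_verbatim(self):
        pwms = parse_motifs(io.StringIO(MEME_TEXT), "meme")
        assert len(pwms) == 1
        np.testing.assert_allclose(
            pwms[0].probs,
            [[0.97, 0.01, 0.01, 0.01], [0.01, 0.97, 0.01, 0.01]],
            atol=1e-9,
        )

    def test_empty_file_gives_empty_library(self):
        assert parse_motifs(io.StringIO(""), "jaspar") == []
        assert parse_motifs(io.StringIO("\n\n"), "meme") == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_motifs(io.StringIO(MEME_TEXT + MEME_TEXT), "meme")

    def test_malformed_meme_names_the_motif(self):
        bad = "MOTIF broken\nletter-probability matrix: alength= 4 w= 1\n0.5 0.5\n"
        with pytest.raises(ValueError, match="broken"):
            parse_motifs(io.StringIO(bad), "meme")

    def test_unknown_dialect(self):
        with pytest.raises(ValueError):
            parse_motifs(io.StringIO(""), "homer")


class TestLogOdds:
    def test_simple_ratios(self, uniform_bg):
        pwm = PWM("m", np.array([[0.5, 0.25, 0.125, 0.125]]))
        lom = log_odds(pwm, uniform_bg)
        assert lom[0, 0] == pytest.approx(1.0)  # log2(0.5/0.25)
        assert lom[0, 1] == pytest.approx(0.0)

    def test_matches_elementwise_formula(self, uniform_bg):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 5)
        lom = log_odds(pwm, uniform_bg)
        np.testing.assert_allclose(lom, np.log2(pwm.probs / 0.25))

    def test_zero_probability_rejected(self, uniform_bg):
        pwm = PWM("m", np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            log_odds(pwm, uniform_bg)


class TestScoreDistribution:
    def test_single_position(self, uniform_bg):
        lom = np.array([[2.0, 0.0, 0.0, 0.0]])
        dist = score_pvalue_distribution(lom, uniform_bg)
        assert dist.pvalue(2.0) == pytest.approx(0.25)
        assert dist.pvalue(-10.0) == 1.0

    @pytest.mark.parametrize("length", [2, 4, 6])
    def test_matches_kmer_enumeration(self, length, uniform_bg):
        rng = np.random.default_rng(length)
        pwm = random_pwm(rng, length)
        lom = log_odds(pwm, uniform_bg)
        dist = score_pvalue_distribution(lom, uniform_bg)
        # brute-force enumeration of all 4^L k-mers
        for threshold in np.percentile(
            [sum(lom[i, k] for i, k in enumerate(kmer))
             for kmer in product(range(4), repeat=length)],
            [5, 50, 95],
        ):
            exact = sum(
                0.25**length
                for kmer in product(range(4), repeat=length)
                if sum(lom[i, k] for i, k in enumerate(kmer))
                >= threshold - dist.bin_width
            )
            assert abs(dist.pvalue(threshold) - exact) <= 4**length * 1e-12 + (
                exact and 0.25**length * length
            )

    def test_nonuniform_background_dinucleotides(self):
        bg = BackgroundModel((0.4, 0.1, 0.1, 0.4))
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 2)
        lom = log_odds(pwm, bg)
        dist = score_pvalue_distribution(lom, bg)
        f = bg.array
        # P(score >= median score) from the 16 dinucleotides
        scores = sorted(
            (lom[0, a] + lom[1, b], f[a] * f[b]) for a in range(4) for b in range(4)
        )
        t = scores[8][0]
        exact = sum(p for s, p in scores if s >= t - dist.bin_width)
        assert dist.pvalue(t) == pytest.approx(exact, abs=1e-9)

    def test_bad_bin_width(self, uniform_bg):
        with pytest.raises(ValueError):
            score_pvalue_distribution(np.zeros((1, 4)), uniform_bg, bin_width=0)


class TestScan:
    def test_consensus_hits_at_origin(self, sharp_pwm, uniform_bg):
        hits = scan(sharp_pwm.consensus, sharp_pwm, uniform_bg, 1e-3)
        assert any(h.interval.start == 0 and h.strand == "+" for h in hits)

    def test_reverse_complement_symmetry(self, sharp_pwm, uniform_bg):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300)) + sharp_pwm.consensus
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = scan(seq, sharp_pwm, uniform_bg, 1e-3)
        rev = scan(rc, sharp_pwm, uniform_bg, 1e-3)
        assert len(fwd) == len(rev)
        assert sorted(h.score for h in fwd) == pytest.approx(
            sorted(h.score for h in rev)
        )

    def test_all_n_sequence_and_short_sequence(self, sharp_pwm, uniform_bg):
        assert scan("N" * 50, sharp_pwm, uniform_bg) == []
        assert scan("ACG", sharp_pwm, uniform_bg) == []

    def test_pvalues_agree_with_distribution(self, uniform_bg):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 6)
        dist = score_pvalue_distribution(log_odds(pwm, uniform_bg), uniform_bg)
        seq = "".join(rng.choice(list("ACGT"), 400))
        for h in scan(seq, pwm, uniform_bg, p_threshold=0.05):
            assert h.pvalue == pytest.approx(dist.pvalue(h.score), abs=1e-12)
            assert h.pvalue <= 0.05


class TestCountHits:
    def test_planted_copies_counted(self, sharp_pwm, uniform_bg):
        rng = np.random.default_rng(3)
        spacer = "".join(rng.choice(list("ACGT"), 40))
        seq = spacer.join([sharp_pwm.consensus] * 3)
        counts = count_hits(seq, [sharp_pwm], uniform_bg, 1e-3)
        assert counts[0] >= 3

    def test_empty_sequence_gives_zero_vector(self, sharp_pwm, uniform_bg):
        assert count_hits("", [sharp_pwm], uniform_bg).tolist() == [0]

    def test_chunking_consistency(self, uniform_bg):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 8)
        seq = "".join(rng.choice(list("ACGT"), 600))
        whole = count_hits(seq, [pwm], uniform_bg, p_threshold=0.01)[0]
        mid = 300
        left = seq[: mid + 7]  # L-1 overlap keeps boundary windows
        right = seq[mid:]
        split = (
            count_hits(left, [pwm], uniform_bg, p_threshold=0.01)[0]
            + count_hits(right, [pwm], uniform_bg, p_threshold=0.01)[0]
        )
        assert whole == split

    def test_scanner_counts_match_scan(self, uniform_bg):
        rng = np.random.default_rng(6)
        lib = [random_pwm(rng, int(rng.integers(5, 11)), f"m{i}") for i in range(8)]
        scanner = MotifScanner(lib, uniform_bg, p_threshold=0.01)
        seq = "".join(rng.choice(list("ACGT"), 500))
        fast = scanner.count_hits(seq)
        slow = [len(scan(seq, p, uniform_bg, 0.01)) for p in lib]
        assert fast.tolist() == slow


class TestMotifGc:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([[1, 0, 0, 0]], 0.0),
            ([[0, 0, 1, 0]], 1.0),
            ([[0, 0.5, 0.5, 0], [1, 0, 0, 0]], 0.5),
        ],
    )
    def test_printed_formula(self, probs, expected):
        assert motif_gc(PWM("m", np.array(probs, dtype=float))) == pytest.approx(expected)


class TestPermutePwm:
    def test_preserves_column_multisets_and_length(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(rng, 7)
        perm = permute_pwm(pwm, np.random.default_rng(42))
        assert len(perm) == len(pwm)
        for i in range(7):
            assert sorted(perm.probs[i]) == pytest.approx(sorted(pwm.probs[i]))

    def test_same_seed_same_output(self):
        pwm = random_pwm(np.random.default_rng(1), 5)
        a = permute_pwm(pwm, np.random.default_rng(7)).probs
        b = permute_pwm(pwm, np.random.default_rng(7)).probs
        np.testing.assert_array_equal(a, b)

    def test_mean_gc_over_permutations_is_half_for_single_column(self):
        # L=1: each of the 4! arrangements equally likely; mean GC over the
        # permutation distribution is (sum of probs)/2 = 0.5
        pwm = PWM("m", np.array([[0.7, 0.1, 0.1, 0.1]]))
        rng = np.random.default_rng(0)
        gcs = [motif_gc(permute_pwm(pwm, rng)) for _ in range(4000)]
        assert np.mean(gcs) == pytest.approx(0.5, abs=0.02)


class TestOverrepresentation:
    def test_identical_count_multisets_give_p_one(self, sharp_pwm, uniform_bg):
        seqs = [sharp_pwm.consensus + "ACGTACGT", "ACGTACGT" + sharp_pwm.consensus]
        stat, p = motif_overrepresentation(seqs, list(seqs), sharp_pwm, uniform_bg)
        assert p == 1.0

    def test_exact_p_matches_rank_split_enumeration(self, sharp_pwm, uniform_bg):
        # counts A = {5,6,7}-ish vs B = {0,0,1}-ish by construction
        spacer = "TTTTTTTT"
        set_a = [spacer.join([sharp_pwm.consensus] * k) for k in (5, 6, 7)]
        set_b = ["A" * 60, "T" * 60, spacer + sharp_pwm.consensus + spacer]
        stat, p = motif_overrepresentation(set_a, set_b, sharp_pwm, uniform_bg, 1e-3)
        # fully separated samples of 3 vs 3: two-sided exact p = 2 / C(6,3)
        assert p == pytest.approx(2 / comb(6, 3))
        assert stat > 0

    def test_swapping_sets_flips_statistic_sign(self, sharp_pwm, uniform_bg):
        set_a = [sharp_pwm.consensus * 3]
        set_b = ["A" * 30]
        s1, p1 = motif_overrepresentation(set_a, set_b, sharp_pwm, uniform_bg, 1e-3)
        s2, p2 = motif_overrepresentation(set_b, set_a, sharp_pwm, uniform_bg, 1e-3)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_empty_set_rejected(self, sharp_pwm, uniform_bg):
        with pytest.raises(ValueError):
            motif_overrepresentation([], ["ACGT"], sharp_pwm, uniform_bg)
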