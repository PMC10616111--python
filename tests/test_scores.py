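"""Coding-potential statistics: ORF score, RRS, Fickett, hexamer, threshold."""

import math

import numpy as np
import pytest

from riboscreen.scores import (
    fickett,
    hexamer_score,
    hexamer_train,
    orf_score,
    orf_score_threshold,
    rrs,
    rrs_from_counts,
)


class TestOrfScore:
    def test_uniform_frames_score_zero(self):
        assert orf_score((10, 10, 10))[0] == 0.0

    def test_hand_evaluated_concentrated_case(self):
        # F=(30,0,0): mean 10, sum of squared deviations / mean = 60
        s, fl = orf_score((30, 0, 0))
        assert s == pytest.approx(math.log2(61), abs=1e-12)
        assert not fl

    def test_sign_flips_when_frame0_not_maximal(self):
        assert orf_score((0, 30, 0))[0] == pytest.approx(-math.log2(61), abs=1e-12)
        assert orf_score((10, 10, 0))[0] < 0  # tie: frame 0 not strictly max

    def test_zero_counts_flagged(self):
        s, fl = orf_score((0, 0, 0))
        assert s == 0.0 and fl == {"zero_ribo"}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            orf_score((1, -1, 0))


class TestRrs:
    def test_printed_formula(self):
        assert rrs(8, 1, 4, 2)[0] == pytest.approx(2.0, abs=1e-12)

    def test_equal_ratios_give_zero(self):
        assert rrs(6, 3, 10, 5)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_flagged_without_value(self):
        val, fl = rrs(8, 0, 4, 2)
        assert val is None and "zero_ribo" in fl

    def test_pseudocount_applied_in_count_space(self):
        # counts (8,1,4,2), equal region lengths/totals: FPKM ratios reduce
        # to count ratios, with 0.5 added to each count first
        val, _ = rrs_from_counts(8, 1, 4, 2, 100, 100, 1000, 1000, pseudocount=0.5)
        assert val == pytest.approx(math.log2((8.5 / 1.5) / (4.5 / 2.5)), abs=1e-12)

    def test_epsilon_zero_reproduces_raw_formula_and_flags_zeros(self):
        val, _ = rrs_from_counts(8, 1, 4, 2, 50, 200, 10**6, 2 * 10**6, pseudocount=0.0)
        exp = math.log2((8 / 50 / (1 / 200)) / (4 / 50 / (2 / 200)))
        assert val == pytest.approx(exp, abs=1e-12)
        val, fl = rrs_from_counts(8, 0, 4, 2, 50, 200, 10**6, 10**6, pseudocount=0.0)
        assert val is None and fl

    def test_missing_utr_flagged(self):
        val, fl = rrs_from_counts(8, 0, 4, 2, 50, 0, 10**6, 10**6)
        assert val is None and "no_utr3" in fl


def fickett_reference(seq):
    """Independent straight-from-tables oracle, coded separately from the
    implementation (numpy, index-based interval lookup)."""
    from riboscreen.fickett_tables import (
        CONTENT_BOUNDS,
        CONTENT_PROB,
        CONTENT_WEIGHT,
        POSITION_BOUNDS,
        POSITION_PROB,
        POSITION_WEIGHT,
    )

    arr = np.frombuffer(seq.encode(), dtype="S1")
    total = 0.0
    for base in "ACGT":
        hits = arr == base.encode()
        by_pos = np.array([hits[k::3].sum() for k in range(3)], dtype=float)
        pos_val = by_pos.max() / (by_pos.min() + 1.0)
        content = hits.mean()
        pi = np.searchsorted(-np.asarray(POSITION_BOUNDS), -pos_val, side="left")
        ci = np.searchsorted(-np.asarray(CONTENT_BOUNDS), -content, side="left")
        pi = min(pi, len(POSITION_BOUNDS) - 1)
        ci = min(ci, len(CONTENT_BOUNDS) - 1)
        total += POSITION_PROB[base][pi] * POSITION_WEIGHT[base]
        total += CONTENT_PROB[base][ci] * CONTENT_WEIGHT[base]
    return total


class TestFickett:
    def test_matches_independent_table_oracle(self, rng):
        assert fickett("ATGATGATGATGATGATG") == pytest.approx(
            fickett_reference("ATGATGATGATGATGATG"), abs=1e-9
        )
        # sanity anchor for the oracle itself: known hand value
        assert fickett_reference("ATGATGATGATGATGATG") == pytest.approx(1.0521, abs=1e-9)
        for n in (9, 30, 120, 300, 301, 302):
            s = "".join(rng.choice(list("ACGT"), size=n))
            assert fickett(s) == pytest.approx(fickett_reference(s), abs=1e-9)
            # concatenation with itself is also scored identically by both
            assert fickett(s + s) == pytest.approx(fickett_reference(s + s), abs=1e-9)

    def test_reverse_complement_changes_value(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=300))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(s))
        assert fickett(s) != fickett(rc)

    def test_short_or_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            fickett("ATGAT")
        with pytest.raises(ValueError):
            fickett("ATGATGNTG")


class TestHexamer:
    def test_identical_corpora_give_all_zero_under_symmetric_counting(self):
        corpus = ["ATGAAACCCGGGTTTTAG", "ATGCCCAAATTTGGGTAG"]
        table = hexamer_train(corpus, corpus, noncoding_step=3)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in table.values())

    def test_absent_hexamer_scores_zero_with_matched_totals(self):
        # 60 nt at step 3 and 24 nt at step 1 both yield 19 hexamers, so the
        # smoothed frequencies of an unseen hexamer coincide: log(f/f) = 0
        coding = ["ATGAAA" * 10]
        noncoding = ["ATGCCCGGGATGCCCGGGATGCCC"]
        table = hexamer_train(coding, noncoding)
        assert table["TTTTTT"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            hexamer_train([], ["ATGAAACCC"])

    def test_all_4096_entries_finite(self, default_sim):
        transcripts, _, truth, _, _ = default_sim
        coding = [
            t.sequence[t.cds[0] : t.cds[1] - 3]
            for t in transcripts
            if t.biotype == "protein_coding"
        ][:10]
        noncoding = [t.sequence for t in transcripts if t.biotype == "lncRNA"][:10]
        table = hexamer_train(coding, noncoding)
        assert len(table) == 4096
        assert all(np.isfinite(v) for v in table.values())

    def test_single_hexamer_identity_and_mean_bound(self):
        table = {h: 0.0 for h in (a + b + c + d + e + f
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 for d in "ACGT" for e in "ACGT" for f in "ACGT")}
        table["ATGAAA"] = 1.2
        assert hexamer_score("ATGAAA", table)[0] == pytest.approx(1.2)
        table["AAATAG"] = -0.6
        s, _ = hexamer_score("ATGAAAAAATAG", table)
        vals = [table["ATGAAA"], table["AAAAAA"], table["AAATAG"]]
        assert min(vals) <= s <= max(vals)
        assert hexamer_score("ATG", table) == (None, {"too_short"})

    def test_coding_like_sequences_score_higher(self, rng):
        # draw hexamer chains from each trained distribution; sign test
        coding = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
        # biased noncoding corpus: AT-rich
        noncoding = ["".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=300))
                     for _ in range(20)]
        table = hexamer_train(coding, noncoding)
        wins = 0
        n = 100
        for _ in range(n):
            sc = hexamer_score("".join(rng.choice(list("ACGT"), size=90)), table)[0]
            sn = hexamer_score("".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=90)), table)[0]
            wins += sc > sn
        from scipy.stats import binomtest

        assert binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.01


class TestThreshold:
    def test_linear_interpolation_on_integers(self):
        assert orf_score_threshold(range(1, 101)) == pytest.approx(5.95, abs=1e-12)

    def test_degenerate_distribution(self):
        assert orf_score_threshold([3.25] * 30) == 3.25

    def test_permutation_invariance(self, rng):
        scores = rng.normal(size=200)
        perm = rng.permutation(scores)
        assert orf_score_threshold(scores) == orf_score_threshold(perm)

    def test_small_calibration_set_errors(self):
        with pytest.raises(ValueError, match="calibration"):
            orf_score_threshold([1.0] * 10)
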