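"""Consensus statistics, conservation columns, annotation intersections."""

import numpy as np
import pytest

from repfam.genome import GenomicInterval
from repfam.stats import (class_family_enrichment,
                          column_deviation, column_entropy_bits,
                          column_statistic, counts_from_trace,
                          intersect_features, length_histogram,
                          max_column_entropy_bits, symbolic_consensus)
from repfam.strands import RepeatHit


def _hit(start, end, record="r", family=1):
    return RepeatHit(record=record, start=start, end=end, strand="+",
                     Z=6.0, family=family)


class TestCountsFromTrace:
    def test_worked_alignment_fragment(self):
        """Columns 21-33 against 'a t c c g g t a c c * c t g' with a column
        deletion opposite the 't' and a base deletion opposite column 30."""
        cols = [21, 22, 23, 24, 25, 26, -1, 27, 28, 29, 30, 31, 32, 33]
        bases = "atccggtacc*ctg"
        s1 = [(-1 if b == "*" else "atcg".index(b)) for b in bases]
        M4 = np.zeros((4, 40))
        counts_from_trace(M4, s1, cols)
        expected_pairs = [("a", 21), ("t", 22), ("c", 23), ("c", 24),
                          ("g", 25), ("g", 26), ("a", 27), ("c", 28),
                          ("c", 29), ("c", 31), ("t", 32), ("g", 33)]
        assert M4.sum() == len(expected_pairs)
        for base, col in expected_pairs:
            assert M4["atcg".index(base), col - 1] == 1
        assert M4[:, 29].sum() == 0  # column 30 faced a deleted base

    def test_column_bound(self):
        with pytest.raises(ValueError):
            counts_from_trace(np.zeros((4, 5)), [0], [9])


class TestColumnDeviation:
    def test_pure_column_hand_values(self):
        """Column (10,0,0,0) with p=0.25 each: w1 = 7.5/sqrt(1.875)."""
        M4u = np.zeros((4, 2))
        M4u[:, 0] = [10, 0, 0, 0]
        M4u[:, 1] = [0, 10, 10, 10]  # makes global p exactly 0.25 each
        wu = column_deviation(M4u)
        assert wu[0, 0] == pytest.approx(7.5 / np.sqrt(1.875))
        assert wu[1, 0] == pytest.approx(-2.5 / np.sqrt(1.875))

    def test_expected_column_gives_zero(self):
        M4 = np.full((4, 6), 2.5)
        assert np.allclose(column_deviation(M4), 0.0)

    def test_multinomial_variance(self, rng):
        """w has unit variance under multinomial sampling at the family's
        base composition."""
        p = np.array([0.25, 0.25, 0.25, 0.25])
        M4 = rng.multinomial(1000, p, size=400).T.astype(float)
        w = column_deviation(M4)
        assert abs(w.var() - 1.0) < 0.2

    def test_residuals_vanish_per_column(self, rng):
        M4 = rng.multinomial(200, [0.4, 0.3, 0.2, 0.1], size=50).T.astype(float)
        w = column_deviation(M4)
        N_j = M4.sum(axis=0)
        p = M4.sum(axis=1) / M4.sum()
        resid = (w * np.sqrt(N_j[None, :] * p[:, None] * (1 - p[:, None])))
        assert np.allclose(resid.sum(axis=0), 0.0, atol=1e-9)


class TestColumnStatistic:
    def test_zero_deviation(self):
        assert column_statistic(np.zeros(4)) == pytest.approx(-np.sqrt(5))

    def test_chi_twelve_point_five(self):
        w = np.array([np.sqrt(12.5), 0, 0, 0])
        assert column_statistic(w) == pytest.approx(5 - np.sqrt(5))

    def test_null_location_and_spread(self, rng):
        """Null distribution of X under multinomial sampling.

        chi(j) sums four cell deviations tied by one linear constraint, so it
        is (4/3) * chi-square_3 with mean 4 (not 3); the Fisher-type
        normalisation sqrt(2 chi) - sqrt(5) therefore centres slightly above
        zero (~ +0.3, from direct simulation) with spread near 1.
        """
        p = np.array([0.25, 0.25, 0.25, 0.25])
        M4 = rng.multinomial(1000, p, size=1000).T.astype(float)
        w = column_deviation(M4)
        X = np.array([column_statistic(w[:, j]) for j in range(w.shape[1])])
        assert abs(X.mean() - 0.31) < 0.15
        assert 0.8 < X.std() < 1.4


class TestConsensus:
    def test_strict_majority(self):
        M4 = np.array([[6.0], [2.0], [1.0], [1.0]])
        assert symbolic_consensus(M4) == "a"

    def test_half_is_not_majority(self):
        M4 = np.array([[5.0], [3.0], [1.0], [1.0]])
        assert symbolic_consensus(M4) == "-"

    def test_empty_column(self):
        assert symbolic_consensus(np.zeros((4, 3))) == "---"

    def test_identical_members_reproduce_sequence(self):
        seq = "atcgga"
        M4 = np.zeros((4, len(seq)))
        for j, b in enumerate(seq):
            M4["atcg".index(b), j] = 42
        assert symbolic_consensus(M4) == seq


class TestEntropy:
    def test_maximum_is_two_bits(self):
        assert max_column_entropy_bits(4) == 2.0
        assert column_entropy_bits([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_pure_column_zero_bits(self):
        assert column_entropy_bits([9, 0, 0, 0]) == 0.0


class TestIntersect:
    def test_half_overlap_not_reported(self):
        # overlap 50 = 50% of the repeat: not > 50%
        hits = [_hit(1, 100)]
        genes = [GenomicInterval("r", 51, 400)]
        assert intersect_features(hits, genes, mode="repeat") == []

    def test_gene_mode_either_side(self):
        hits = [_hit(1, 100)]
        genes = [GenomicInterval("r", 1, 60)]
        # overlap 60 > 50% of both repeat (100) and gene (60)
        pairs = intersect_features(hits, genes, mode="gene")
        assert pairs == [(0, 0, 60)]

    def test_gene_mode_covers_small_feature(self):
        hits = [_hit(1, 1000)]
        genes = [GenomicInterval("r", 100, 160)]
        # only 61/1000 of the repeat, but >50% of the gene
        assert intersect_features(hits, genes, mode="gene")
        assert intersect_features(hits, genes, mode="repeat") == []

    def test_disjoint(self):
        assert intersect_features([_hit(1, 50)],
                                  [GenomicInterval("r", 100, 200)]) == []

    def test_many_to_many(self):
        hits = [_hit(1, 100), _hit(20, 120)]
        genes = [GenomicInterval("r", 1, 90), GenomicInterval("r", 30, 110)]
        pairs = intersect_features(hits, genes, mode="gene")
        assert len(pairs) == 4

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            intersect_features([], [], mode="nope")


class TestEnrichment:
    def test_hand_arithmetic_single_cell(self):
        """2 classes x 2 families, all 10 pairs in one cell: frozen v'."""
        pairs = [("A", 1)] * 10 + [("A", 2), ("B", 1), ("B", 2)]
        m = class_family_enrichment(pairs)
        V = m.V.values
        n = 13
        x, y = V.sum(axis=1), V.sum(axis=0)
        p = x[0] * y[0] / n**2
        expected = (10 - n * p) / np.sqrt(n * p * (1 - p))
        assert m.v_prime.values[0, 0] == pytest.approx(expected)

    def test_degenerate_single_cell(self):
        m = class_family_enrichment([("A", 1)] * 5)
        assert m.v_prime.values[0, 0] == 0.0  # p = 1 -> standardised to 0

    def test_null_rarely_exceeds_three(self, rng):
        """Independent margins: |v'| > 3 in ~<1% of cells."""
        exceed, total = 0, 0
        for _ in range(60):
            classes = rng.integers(0, 5, size=400)
            fams = rng.integers(0, 8, size=400)
            m = class_family_enrichment(list(zip(classes, fams)))
            vp = m.v_prime.values
            exceed += (np.abs(vp) > 3).sum()
            total += vp.size
        assert exceed / total < 0.01

    def test_empty(self):
        m = class_family_enrichment([])
        assert m.V.empty

    def test_flagging(self):
        pairs = [("A", 1)] * 30 + [("B", 2)] * 30 + [("A", 2), ("B", 1)]
        flags = class_family_enrichment(pairs).flagged()
        assert flags.loc["A", 1] == "+"
        assert flags.loc["A", 2] == "-"


class TestLengthHistogram:
    def test_summary_extremes(self):
        hits = [_hit(1, 108), _hit(200, 799), _hit(1000, 1521)]
        _, summary = length_histogram(hits)
        assert (summary["min"], summary["max"]) == (108, 600)
        assert summary["mean"] == pytest.approx((108 + 600 + 522) / 3)

    def test_single_hit(self):
        _, summary = length_histogram([_hit(10, 59)])
        assert summary["mean"] == 50

    def test_empty(self):
        table, summary = length_histogram([])
        assert table.empty and summary == {}
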