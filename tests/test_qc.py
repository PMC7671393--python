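"""Concordance statistics: worked examples and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilift import BedRecord
from epilift.qc import (
    Contingency2x2,
    bin_beta,
    bin_coverage,
    cohen_kappa,
    delta_methylation,
    enrichment_test,
    fisher_one_sided,
    gain_loss_overlap,
    jaccard,
    nearest_feature_delta,
    odds_ratio,
    pearson_width_correlation,
    width_change_classify,
)


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by direct binomial-coefficient enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n, row1)
    lo, hi = a, min(row1, col1)
    return sum(
        math.comb(col1, k) * math.comb(n - col1, row1 - k) for k in range(lo, hi + 1)
    ) / denom


class TestJaccard:
    def test_identity(self):
        a = {"chr1": [(0, 10), (20, 30)]}
        assert jaccard(a, a) == 1.0

    def test_disjoint(self):
        assert jaccard({"chr1": [(0, 10)]}, {"chr1": [(50, 60)]}) == 0.0

    def test_worked_example(self):
        assert jaccard({"c": [(0, 10)]}, {"c": [(5, 15)]}) == pytest.approx(1 / 3)

    def test_symmetry_and_bedrecord_input(self):
        a = [BedRecord("chr1", 0, 10)]
        b = [BedRecord("chr1", 5, 15)]
        assert jaccard(a, b) == jaccard(b, a)

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            jaccard({}, {})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 80), st.integers(1, 20)),
                    min_size=1, max_size=8))
    def test_shrinking_symmetric_difference_raises_jaccard(self, raw):
        a = {"c": [(s, s + w) for s, w in raw]}
        b = {"c": [(s + 1, s + w + 1) for s, w in raw]}
        j_ab = jaccard(a, b)
        assert 0.0 <= j_ab <= 1.0
        assert jaccard(a, a) >= j_ab


class TestGainLossOverlap:
    def test_worked_example(self):
        align = {"c": [(0, 10), (20, 30)]}
        lift = {"c": [(5, 12), (40, 50)]}
        out = gain_loss_overlap(align, lift)
        assert (out["loss"], out["gain"]) == (1, 1)
        assert out["overlap_align"] == out["overlap_lift"] == 1

    def test_identical_sets_all_overlap(self):
        a = {"c": [(0, 10), (20, 30)]}
        out = gain_loss_overlap(a, a)
        assert out["pct_overlap"] == 100.0 and out["loss"] == out["gain"] == 0

    def test_empty_liftover_all_loss(self):
        out = gain_loss_overlap({"c": [(0, 10)]}, {})
        assert out["loss"] == 1 and out["gain"] == 0

    def test_count_identities(self):
        align = {"c": [(0, 10), (20, 30), (100, 110)]}
        lift = {"c": [(5, 12), (200, 210)]}
        out = gain_loss_overlap(align, lift)
        assert out["overlap_align"] + out["loss"] == 3
        assert out["overlap_lift"] + out["gain"] == 2


class TestWidthChange:
    def test_worked_examples(self):
        out = width_change_classify([(10, 12), (2, 7), (30, 10)])
        assert out == {"shrink": 1, "equal": 1, "extend": 1}

    def test_boundaries_are_changed_classes(self):
        out = width_change_classify([(20, 10), (10, 20)])  # ratios 2 and 1/2
        assert out == {"shrink": 1, "equal": 0, "extend": 1}

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            width_change_classify([(0, 5)])


class TestBins:
    @pytest.mark.parametrize(
        "value,bin_", [(0, 0), (5.9, 0), (6, 1), (12, 2), (24, 4), (32, 4)]
    )
    def test_coverage_edges(self, value, bin_):
        assert bin_coverage(value) == bin_

    def test_coverage_above_top_is_flagged(self):
        with pytest.warns(UserWarning):
            assert bin_coverage(40) == 4

    @pytest.mark.parametrize(
        "value,bin_", [(0.0, 0), (0.2, 1), (0.59, 2), (0.8, 4), (1.0, 4)]
    )
    def test_beta_edges(self, value, bin_):
        assert bin_beta(value) == bin_

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_coverage(-1)


class TestKappa:
    def test_perfect_agreement(self):
        r = cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1])
        assert r.kappa == 1.0 and r.interpretation == "perfect agreement"

    def test_worked_confusion_table(self):
        # [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5, kappa = 0.8
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        r = cohen_kappa(a, b)
        assert r.kappa == pytest.approx(0.8)
        assert r.interpretation == "substantial agreement"

    def test_constant_rater_gives_zero(self):
        a = [0] * 10
        b = [0] * 5 + [1] * 5
        assert cohen_kappa(a, b).kappa == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        a = [0, 0, 1, 1, 2, 2, 0, 1]
        b = [0, 1, 1, 1, 2, 0, 0, 1]
        relabel = {0: "x", 1: "y", 2: "z"}
        k1 = cohen_kappa(a, b).kappa
        k2 = cohen_kappa([relabel[v] for v in a], [relabel[v] for v in b]).kappa
        assert k1 == pytest.approx(k2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])


class TestDelta:
    def test_significant_positive(self):
        out = delta_methylation([("c", 1, 0.9)], [("c", 1, 0.6)])
        assert out["deltas"][("c", 1)] == pytest.approx(0.3)
        assert ("c", 1) in out["significant"]

    def test_zero_not_significant(self):
        out = delta_methylation([("c", 1, 0.5)], [("c", 1, 0.5)])
        assert out["significant"] == set()
        assert out["fraction_zero"] == 1.0

    def test_boundary_negative_is_significant(self):
        out = delta_methylation([("c", 1, 0.1)], [("c", 1, 0.3)])
        assert out["deltas"][("c", 1)] == pytest.approx(-0.2)
        assert ("c", 1) in out["significant"]

    def test_unmatched_sites_counted(self):
        out = delta_methylation(
            [("c", 1, 0.5), ("c", 2, 0.5)], [("c", 1, 0.5), ("c", 9, 0.1)]
        )
        assert out["n_common"] == 1
        assert out["n_lift_only"] == 1 and out["n_align_only"] == 1


class TestFisher:
    def test_worked_table(self):
        # tail = [C(10,8)C(10,2)+C(10,9)C(10,1)+C(10,10)C(10,0)]/C(20,10)
        p = fisher_one_sided(Contingency2x2(8, 2, 2, 8))
        assert p == pytest.approx(2126 / 184756)
        orr, corrected = odds_ratio(Contingency2x2(8, 2, 2, 8))
        assert orr == 16.0 and not corrected

    def test_zero_cell_continuity_correction(self):
        orr, corrected = odds_ratio(Contingency2x2(5, 0, 0, 5))
        assert corrected and orr == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_matches_scipy_two_by_two(self):
        from scipy.stats import fisher_exact

        for table in [(3, 7, 6, 4), (10, 0, 2, 8), (1, 1, 1, 1)]:
            p = fisher_one_sided(Contingency2x2(*table))
            ref = fisher_exact(
                [[table[0], table[1]], [table[2], table[3]]],
                alternative="greater",
            )[1]
            assert p == pytest.approx(ref)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        p = fisher_one_sided(Contingency2x2(a, b, c, d))
        assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d))


class TestEnrichment:
    def annotations(self):
        return {"feat": {"c": [(0, 100)]}, "empty": {"c": [(5000, 5100)]}}

    def test_seeded_reproducibility(self):
        query = {"c": [(i, i + 1) for i in range(0, 200, 2)]}
        universe = {"c": np.arange(0, 4000, 2)}
        r1 = enrichment_test(query, self.annotations(), universe, seed=11)
        r2 = enrichment_test(query, self.annotations(), universe, seed=11)
        assert r1 == r2

    def test_query_in_annotation_universe_outside_is_enriched(self):
        query = {"c": [(i, i + 1) for i in range(0, 100, 2)]}
        universe = {"c": np.arange(1000, 9000, 2)}
        (res, _empty) = enrichment_test(
            query, {"feat": {"c": [(0, 100)]}, "x": {"c": [(9500, 9600)]}},
            universe, seed=3,
        )
        assert res.table.a == 50 and res.table.c == 0
        assert res.continuity_corrected and res.significant

    def test_interval_query_uses_chrom_sizes(self):
        query = {"c": [(10, 60), (100, 150)]}
        res = enrichment_test(
            query, {"feat": {"c": [(0, 200)]}}, {"c": 100_000},
            seed=5,
        )
        assert res[0].table.a == 2

    def test_universe_smaller_than_query_rejected(self):
        query = {"c": [(i, i + 1) for i in range(50)]}
        with pytest.raises(ValueError, match="universe"):
            enrichment_test(query, {"f": {"c": [(0, 5)]}},
                            {"c": np.arange(10)}, seed=0)


class TestNearestFeature:
    def test_edge_distance(self):
        points = [("chrA", 5)]
        feats = [("chrA", 8, 12)]
        res, zero_frac, skipped = nearest_feature_delta(
            points, feats, [("chrA", 5)], feats
        )
        assert res[0].d1 == 3 and res[0].d2 == 3 and res[0].delta == 0
        assert zero_frac == 1.0 and skipped == 0

    def test_identity_lift_all_zero(self):
        points = [("chrA", 5), ("chrA", 40)]
        feats = [("chrA", 8, 12), ("chrA", 50, 60)]
        res, zero_frac, _ = nearest_feature_delta(points, feats, points, feats)
        assert zero_frac == 1.0

    def test_deletion_between_point_and_feature_shifts_delta(self):
        # a 7 bp source-only deletion between the point and the feature:
        # target coordinates of the feature move 7 bp closer
        points = [("chrA", 5)]
        feats_src = [("chrA", 20, 30)]
        feats_tgt = [("chrA", 13, 23)]
        res, zero_frac, _ = nearest_feature_delta(
            points, feats_src, [("chrA", 5)], feats_tgt
        )
        assert res[0].d1 == 15 and res[0].d2 == 8
        assert res[0].delta == 7 and zero_frac == 0.0

    def test_covered_point_skipped(self):
        res, zero_frac, skipped = nearest_feature_delta(
            [("chrA", 9)], [("chrA", 8, 12)], [("chrA", 9)], [("chrA", 8, 12)]
        )
        assert res == [] and skipped == 1


class TestPearson:
    def test_identical(self):
        assert pearson_width_correlation([(1, 1), (2, 2), (3, 3)]) == pytest.approx(1.0)

    def test_negated(self):
        assert pearson_width_correlation(
            [(1, 3), (2, 2), (3, 1)]
        ) == pytest.approx(-1.0)

    def test_linear_scaling(self):
        assert pearson_width_correlation(
            [(1, 2), (2, 4), (3, 6)]
        ) == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_width_correlation([(1, 5), (2, 5)])
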