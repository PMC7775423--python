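import math

import numpy as np
import pytest
from scipy import stats as sps

from tmdmap.method_stats import (
    DEFAULT_BIN_LABELS,
    TMDBinHistogram,
    binomial_enrichment,
    chi_square_gof,
    histogram_from_counts,
    per_bin_ttest,
    replicate_reproducibility,
    tmd_histogram,
)
from tmdmap.tmd_mapping import ProteinGroup


def _group(gid, *members, peps=("A",)):
    return ProteinGroup(gid, tuple(sorted(members or (gid,))), frozenset(peps))


class TestHistogram:
    def test_counts_and_fractions(self):
        groups = [_group("P1"), _group("P2"), _group("P3")]
        counts = {"P1": 1, "P2": 1, "P3": 2}
        hist = tmd_histogram(groups, counts)
        assert hist.counts[0] == 2 and hist.counts[1] == 1
        assert hist.fractions[0] == pytest.approx(2 / 3)
        assert hist.fractions[1] == pytest.approx(1 / 3)
        assert sum(hist.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_open_bin_collects_large_counts(self):
        hist = histogram_from_counts([12, 30])
        assert hist.counts[-1] == 2 and hist.total == 2

    def test_zero_tmd_reported_separately(self):
        hist = histogram_from_counts([0, 0, 3])
        assert hist.n_zero_tmd == 2 and hist.total == 1

    def test_no_tmps_flagged(self, caplog):
        hist = tmd_histogram([_group("P1")], {"P1": 0})
        assert hist.total == 0
        assert all(math.isnan(f) for f in hist.fractions)

    def test_group_count_is_max_over_members(self):
        groups = [_group("P1", "P1", "P2")]
        hist = tmd_histogram(groups, {"P1": 1, "P2": 7})
        assert hist.counts[6] == 1  # bin "7"


class TestChiSquare:
    def test_identity_gives_zero_statistic(self):
        observed = TMDBinHistogram(("1", "2"), (10, 10))
        expected = TMDBinHistogram(("1", "2"), (50, 50))
        res = chi_square_gof(observed, expected)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # O = [20, 0], E proportions 1/2,1/2 over n=20 -> sum (O-E)^2/E = 20
        observed = TMDBinHistogram(("1", "2"), (20, 0))
        expected = TMDBinHistogram(("1", "2"), (10, 10))
        res = chi_square_gof(observed, expected)
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1
        assert res.pvalue == pytest.approx(sps.chi2.sf(20.0, 1))

    def test_hand_computed_three_bins(self):
        observed = TMDBinHistogram(("1", "2", "3"), (30, 60, 10))
        expected = TMDBinHistogram(("1", "2", "3"), (25, 50, 25))
        res = chi_square_gof(observed, expected)
        hand = sum(
            (o - e) ** 2 / e for o, e in zip((30, 60, 10), (25, 50, 25))
        )
        assert res.statistic == pytest.approx(hand)
        assert res.dof == 2

    def test_small_expected_bins_merged_rightward(self):
        observed = TMDBinHistogram(("1", "2", "3"), (96, 3, 1))
        expected = TMDBinHistogram(("1", "2", "3"), (96, 3, 1))
        res = chi_square_gof(observed, expected)
        # bins 2 and 3 each expect < 5 and collapse into bin 1
        assert res.dof == 0 or res.merge_log  # merges logged
        assert len(res.merged_labels) < 3

    def test_all_zero_observed_errors(self):
        with pytest.raises(ValueError):
            chi_square_gof(
                TMDBinHistogram(("1",), (0,)), TMDBinHistogram(("1",), (5,))
            )

    def test_mismatched_bins_error(self):
        with pytest.raises(ValueError):
            chi_square_gof(
                TMDBinHistogram(("1",), (5,)),
                TMDBinHistogram(("2",), (5,)),
            )


class TestReproducibility:
    def test_worked_example(self):
        res = replicate_reproducibility([{"A", "B"}, {"B", "C"}, {"B"}])
        assert res.percentage == pytest.approx(100 / 3)
        assert res.n_common == 1 and res.n_union == 3

    def test_identical_sets_are_fully_reproducible(self):
        res = replicate_reproducibility([{"A", "B"}] * 3)
        assert res.percentage == pytest.approx(100.0)

    def test_disjoint_sets_are_zero(self):
        res = replicate_reproducibility([{"A"}, {"B"}])
        assert res.percentage == 0.0

    def test_order_invariance_and_range(self):
        sets = [{"A", "B", "C"}, {"B", "C", "D"}, {"C"}]
        a = replicate_reproducibility(sets)
        b = replicate_reproducibility(list(reversed(sets)))
        assert a.percentage == b.percentage
        assert 0.0 <= a.percentage <= 100.0

    def test_venn_counts_partition_the_union(self):
        sets = [{"A", "B"}, {"B", "C"}, {"B", "D"}]
        res = replicate_reproducibility(sets)
        assert sum(c for _, c in res.venn_counts) == res.n_union
        venn = dict(res.venn_counts)
        assert venn[(0, 1, 2)] == 1  # B everywhere

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            replicate_reproducibility([set(), set()])


class TestPerBinTTest:
    def test_identical_replicates_give_p_one(self):
        fracs = {"1": [0.5, 0.4, 0.6]}
        (res,) = per_bin_ttest(fracs, {"1": [0.5, 0.4, 0.6]})
        assert res.pvalue == pytest.approx(1.0)
        assert res.stars == ""

    def test_zero_variance_equal_means_degenerate(self):
        (res,) = per_bin_ttest({"1": [0.5, 0.5, 0.5]}, {"1": [0.5, 0.5, 0.5]})
        assert res.pvalue == 1.0 and res.degenerate

    def test_zero_variance_unequal_means_degenerate_zero(self):
        (res,) = per_bin_ttest({"1": [0.2, 0.2]}, {"1": [0.5, 0.5]})
        assert res.pvalue == 0.0 and res.degenerate

    def test_clear_separation_is_significant(self):
        a, b = [0.2, 0.21, 0.19], [0.5, 0.51, 0.49]
        (res,) = per_bin_ttest({"1": a}, {"1": b})
        # classical Student t computed from the textbook formula
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_hand = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert res.pvalue == pytest.approx(p_hand)
        assert res.pvalue < 0.01 and res.stars == "**"

    def test_mismatched_bins_error(self):
        with pytest.raises(ValueError):
            per_bin_ttest({"1": [0.1, 0.2]}, {"2": [0.1, 0.2]})


class TestBinomialEnrichment:
    def test_exactly_proportional_counts_give_p_one(self):
        rows = binomial_enrichment({"c": 10}, 100, {"c": 10}, 100)
        assert rows[0].pvalue == pytest.approx(1.0)

    def test_extreme_depletion_is_tiny(self):
        rows = binomial_enrichment({"c": 0}, 100, {"c": 50}, 100)
        # independent tail computation: two-sided exact binomial at p0=0.25
        pmf0 = sps.binom.pmf(0, 100, 0.25)
        k = np.arange(101)
        p_hand = sps.binom.pmf(k, 100, 0.25)[
            sps.binom.pmf(k, 100, 0.25) <= pmf0 * (1 + 1e-12)
        ].sum()
        assert rows[0].pvalue == pytest.approx(p_hand, rel=1e-6)
        assert rows[0].pvalue < 1e-3
        assert rows[0].direction == "B"

    def test_single_category_q_equals_p(self):
        rows = binomial_enrichment({"c": 5}, 50, {"c": 1}, 50)
        assert rows[0].qvalue == pytest.approx(rows[0].pvalue)

    def test_direction_matches_proportion_difference(self):
        rows = binomial_enrichment(
            {"up": 30, "down": 5}, 100, {"up": 10, "down": 20}, 100
        )
        by_cat = {r.category: r for r in rows}
        assert by_cat["up"].direction == "A"
        assert by_cat["down"].direction == "B"
        assert all(0.0 < r.pvalue <= 1.0 for r in rows)

    def test_absent_category_skipped_and_bad_totals_error(self):
        assert binomial_enrichment({"c": 0}, 10, {"c": 0}, 10) == []
        with pytest.raises(ValueError):
            binomial_enrichment({"c": 1}, 0, {"c": 1}, 10)
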