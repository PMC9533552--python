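"""Nonparametric tests, outlier rule, aggregation, and summaries."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retquant import demographics
from retquant.stats import (
    ComparisonResult,
    aggregate,
    compare_groups,
    detect_outliers,
    paired_coloc_test,
    rank_sum_test,
    signed_rank_test,
    significance_summary,
    stars,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (pure python, used only by tests)
# ---------------------------------------------------------------------------

def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = r
        i = j
    return ranks


def brute_rank_sum_p(x, y):
    """Enumerate every assignment of the observed midranks to group 1."""
    vals = list(x) + list(y)
    ranks = _midranks(vals)
    n, N = len(x), len(vals)
    w = sum(ranks[:n])
    mu = n * (N + 1) / 2.0
    hits = total = 0
    for comb in combinations(range(N), n):
        s = sum(ranks[i] for i in comb)
        hits += abs(s - mu) >= abs(w - mu)
        total += 1
    return hits / total


def brute_signed_rank_p(diffs):
    """Enumerate all sign patterns of the nonzero differences' midranks."""
    d = [v for v in diffs if v != 0]
    if not d:
        return 1.0
    ranks = _midranks([abs(v) for v in d])
    t = sum(r if v > 0 else -r for v, r in zip(d, ranks))
    hits = total = 0
    for signs in product((1, -1), repeat=len(d)):
        s = sum(sg * r for sg, r in zip(signs, ranks))
        hits += abs(s) >= abs(t)
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_separated_triples_exact_p(self):
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.100)

    def test_identical_groups_no_evidence(self):
        w, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0
        assert w == pytest.approx(10.5)  # null center n(N+1)/2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    def test_symmetry_in_group_order(self):
        x, y = [3, 1, 4, 1, 5], [9, 2, 6, 5]
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])

    def test_asymptotic_branch_matches_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.integers(0, 10, 15).astype(float)
        y = rng.integers(0, 10, 12).astype(float)
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(
            mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 7))
        n2 = int(rng.integers(1, 8 - n1 + 1))
        x = rng.integers(0, 5, n1).tolist()
        y = rng.integers(0, 5, n2).tolist()
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# signed-rank
# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_all_positive_differences_exact_p(self):
        t, p = signed_rank_test([5, 4, 6, 5, 7])
        assert t == 15.0
        assert p == pytest.approx(2 / 32)

    def test_all_zero_differences_uninformative(self):
        _, p = signed_rank_test([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_zeros_dropped_before_ranking(self):
        _, p_with = signed_rank_test([0, 5, 4, 6, 5, 7])
        _, p_without = signed_rank_test([5, 4, 6, 5, 7])
        assert p_with == p_without

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.integers(-3, 4, int(rng.integers(3, 9))).tolist()
        _, p = signed_rank_test(d)
        assert p == pytest.approx(brute_signed_rank_p(d), abs=1e-12)


# ---------------------------------------------------------------------------
# outlier removal
# ---------------------------------------------------------------------------

class TestOutliers:
    def test_gross_outlier_excluded(self):
        keep = detect_outliers([1, 2, 3, 100])
        assert keep.tolist() == [True, True, True, False]

    def test_zero_spread_keeps_everything(self):
        assert detect_outliers([5, 5, 5, 5]).all()

    def test_below_minimum_n_no_exclusion(self):
        assert detect_outliers([1, 2]).all()

    def test_masked_outliers_removed_by_iteration(self):
        # the extreme value masks the moderate one on the first pass
        keep = detect_outliers([1, 1, 1, 1, 1, 1, 50, 1000])
        assert keep.tolist() == [True] * 6 + [False, False]

    def test_nan_values_never_kept(self):
        keep = detect_outliers([1.0, np.nan, 2.0, 3.0])
        assert not keep[1]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=12))
    def test_idempotent_fixed_point(self, values):
        values = np.asarray(values)
        keep = detect_outliers(values)
        again = detect_outliers(values[keep])
        assert again.all()


# ---------------------------------------------------------------------------
# aggregation and comparisons
# ---------------------------------------------------------------------------

def _rows(donor, group, region, layer, values):
    return [
        {"donor_id": donor, "group": group, "region": region, "layer": layer,
         "section": 1 + i // 2, "image": 1 + i % 2, "percent": v}
        for i, v in enumerate(values)
    ]


class TestAggregate:
    def test_data_point_is_mean_over_images(self):
        rows = pd.DataFrame(_rows("D1", "AD", "central", "GCL", [10, 20, 30, 40]))
        points = aggregate(rows, "percent")
        assert len(points) == 1
        assert points.iloc[0]["percent"] == 25.0
        assert points.iloc[0]["n_images"] == 4

    def test_excluded_image_layer_drops_from_mean(self):
        rows = pd.DataFrame(_rows("D1", "AD", "central", "GCL", [10, 20, 30]))
        points = aggregate(rows, "percent")
        assert points.iloc[0]["percent"] == 20.0
        assert points.iloc[0]["n_images"] == 3

    def test_layer_group_mode_pools_layers(self):
        rows = pd.DataFrame(
            _rows("D1", "AD", "central", "RNFL", [10.0]) +
            _rows("D1", "AD", "central", "INL", [30.0])
        )
        points = aggregate(rows, "percent", mode="layer-group")
        by_key = points.set_index("key")["percent"]
        assert by_key["inner"] == 10.0 and by_key["outer"] == 30.0


def _points(values_by_group, region="central", key="GCL"):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append({"donor_id": f"{group}{i}", "group": group, "region": region,
                         "key": key, "percent": v, "n_images": 4})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_separated_groups_significant(self):
        pts = _points({"AD": [4, 5, 6, 7, 8], "control": [1, 1.5, 2, 2.5, 3, 3.5, 2.2]})
        res = compare_groups(pts, "central", "GCL")
        assert res.computable
        assert res.p_value < 0.05
        assert res.group_stats["AD"]["mean"] == pytest.approx(6.0)
        assert res.group_stats["AD"]["n"] == 5

    def test_outlier_excluded_and_logged(self):
        pts = _points({"AD": [4, 5, 6, 1000], "control": [1, 2, 3, 2]})
        res = compare_groups(pts, "central", "GCL")
        assert res.excluded["AD"] == [1000.0]
        assert res.group_stats["AD"]["n"] == 3

    def test_empty_group_not_computable(self):
        pts = _points({"AD": [4, 5, 6], "control": []})
        res = compare_groups(pts, "central", "GCL")
        assert not res.computable and res.p_value is None


class TestPairedColoc:
    def _pts(self, pos, neg, group="control"):
        rows = [
            {"donor_id": f"d{i}", "group": group, "region": "central", "key": "GCL",
             "p_pos": p, "p_neg": q, "n_images": 4}
            for i, (p, q) in enumerate(zip(pos, neg))
        ]
        return pd.DataFrame(rows)

    def test_consistent_enrichment_detected(self):
        # 7 donors, all differences positive: exact p = 2/2^7 < 0.05
        pts = self._pts([10, 11, 12, 10, 13, 12, 11], [5, 7, 6, 5, 6, 8, 7])
        res = paired_coloc_test(pts, "central", "GCL", "control")
        assert res.p_value == pytest.approx(2 / 128)
        assert res.note == "significant colocalization"

    def test_five_consistent_pairs_exact_p(self):
        pts = self._pts([10, 11, 12, 10, 13], [5, 7, 6, 5, 6])
        res = paired_coloc_test(pts, "central", "GCL", "control")
        assert res.p_value == pytest.approx(2 / 32)

    def test_all_zero_differences_flagged(self):
        pts = self._pts([5, 5, 5], [5, 5, 5])
        res = paired_coloc_test(pts, "central", "GCL", "control")
        assert res.p_value == 1.0
        assert "zero" in res.note

    def test_too_few_pairs_not_computable(self):
        pts = self._pts([10, 11], [5, 6])
        res = paired_coloc_test(pts, "central", "GCL", "control")
        assert not res.computable


class TestSummary:
    def test_star_tiers(self):
        assert stars(0.004) == "**"
        assert stars(0.03) == "*"
        assert stars(0.0004) == "***"
        assert stars(0.2) == ""

    def test_counts_of_significant_geo_layers(self):
        results = [
            ComparisonResult("central", k, "signed-rank", 1.0, p, True)
            for k, p in [("RNFL", 0.01), ("GCL", 0.2), ("IPL", 0.04), ("INL", 0.5)]
        ]
        df = significance_summary(results)
        assert df.attrs["n_significant"] == 2
        assert df.attrs["n_total"] == 4

    def test_empty_result_set(self):
        df = significance_summary([])
        assert df.attrs["n_significant"] == 0 and df.attrs["n_total"] == 0


class TestDemographics:
    def test_printed_age_means_and_contrast(self):
        s = demographics.age_summary()
        assert s["control_mean_age"] == pytest.approx(74.8)
        assert s["n_control"] == 10 and s["n_ad"] == 9
        assert s["ad_mean_age"] == pytest.approx(77.667, abs=1e-3)
        assert s["p_value"] > 0.05  # age-matched groups
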