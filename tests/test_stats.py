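"""Nonparametric statistics, validated against exhaustive enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalconn.stats import (
    benjamini_hochberg,
    compare_groups,
    kruskal_wallis,
    mann_whitney_u,
    pearson_r,
    summarize_groups,
)


def exact_mwu_p(a, b):
    """Two-sided Mann-Whitney p by full permutation enumeration."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_min(sample_a, sample_b):
        u = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in sample_a
            for y in sample_b
        )
        return min(u, len(sample_a) * len(sample_b) - u)

    observed = u_min(a, b)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_min(sa, sb) <= observed + 1e-12:
            hits += 1
    return hits / total


def exact_kw_p(groups):
    """Kruskal-Wallis p by full permutation enumeration of group labels."""
    sizes = [len(v) for v in groups.values()]
    pooled = [x for v in groups.values() for x in v]

    def h_stat(partition):
        flat = [x for part in partition for x in part]
        order = sorted(range(len(flat)), key=lambda i: flat[i])
        ranks = [0.0] * len(flat)
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and flat[order[j]] == flat[order[i]]:
                j += 1
            r = (i + j + 1) / 2.0
            for k in range(i, j):
                ranks[order[k]] = r
            i = j
        n = len(flat)
        pos = 0
        h = 0.0
        for part in partition:
            rsum = sum(ranks[pos : pos + len(part)])
            h += rsum**2 / len(part)
            pos += len(part)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        ties = {}
        for x in flat:
            ties[x] = ties.get(x, 0) + 1
        corr = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
        return h / corr if corr > 0 else float("nan")

    observed = h_stat(list(groups.values()))
    hits = total = 0
    for perm in itertools.permutations(pooled):
        parts = []
        pos = 0
        for s in sizes:
            parts.append(list(perm[pos : pos + s]))
            pos += s
        total += 1
        if h_stat(parts) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestKruskalWallis:
    def test_hand_evaluated_h(self):
        h, _ = kruskal_wallis({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert h == pytest.approx(4.571, abs=5e-4)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            groups = {g: rng.standard_normal(6).tolist() for g in "abc"}
            ps.append(kruskal_wallis(groups)[1])
        assert 0.35 < np.mean(ps) < 0.65
        assert (np.asarray(ps) < 0.05).mean() < 0.12

    def test_two_groups_matches_mwu_chi2(self):
        # with 2 groups, H equals the squared normal MWU z-statistic
        import scipy.stats

        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 3.0, 8.0, 12.0, 15.0]
        h, p = kruskal_wallis({"a": a, "b": b})
        z = scipy.stats.norm.isf(
            scipy.stats.mannwhitneyu(a, b, method="asymptotic",
                                     use_continuity=False).pvalue / 2
        )
        assert h == pytest.approx(z**2, rel=1e-6)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestMannWhitney:
    def test_fully_separated(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_tie_counting(self):
        u, _ = mann_whitney_u([1, 2], [1, 2])
        assert u == 2.0

    def test_symmetry(self, rng):
        a = rng.standard_normal(8).tolist()
        b = (rng.standard_normal(6) + 0.5).tolist()
        assert mann_whitney_u(a, b) == mann_whitney_u(b, a)

    @pytest.mark.parametrize("seed", range(6))
    def test_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 5))
        n_b = int(rng.integers(2, 9 - n_a))
        a = rng.standard_normal(n_a).round(2).tolist()
        b = rng.standard_normal(n_b).round(2).tolist()
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(exact_mwu_p(a, b), abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKwPermutation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_close_to_enumeration_at_tiny_n(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            "a": rng.standard_normal(3).round(2).tolist(),
            "b": rng.standard_normal(2).round(2).tolist(),
            "c": rng.standard_normal(2).round(2).tolist(),
        }
        _, p_chi2 = kruskal_wallis(groups)
        p_exact = exact_kw_p(groups)
        # chi-squared approximation at n=7 is coarse; same order of magnitude
        assert abs(p_chi2 - p_exact) < 0.12


class TestBenjaminiHochberg:
    def test_all_rejected(self):
        assert benjamini_hochberg([0.001, 0.02, 0.04], q=0.05) == [True] * 3

    def test_none_rejected(self):
        assert benjamini_hochberg([0.04, 0.5, 0.9], q=0.05) == [False] * 3

    def test_empty(self):
        assert benjamini_hochberg([]) == []

    def test_step_up_threshold_by_hand(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05:
        # largest i with p_(i) <= i*q/m is i=2 (0.040 > 0.0375)
        flags = benjamini_hochberg([0.011, 0.024, 0.040, 0.06], q=0.05)
        assert flags == [True, True, False, False]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        st.integers(min_value=0, max_value=7),
    )
    def test_monotone_in_pvalues(self, pvals, which):
        which = which % len(pvals)
        before = benjamini_hochberg(pvals, q=0.05)
        lowered = list(pvals)
        lowered[which] = lowered[which] / 2.0
        after = benjamini_hochberg(lowered, q=0.05)
        for i, was in enumerate(before):
            if was:
                assert after[i]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_worked_five_points(self):
        r, _ = pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 7])
        assert r == pytest.approx(0.8241633836921342)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummaries:
    def test_odd_group_exact_order_statistic(self):
        med, q25, q75 = summarize_groups({"g": list(range(1, 16))})["g"]
        assert med == 8.0

    def test_even_group_interpolated(self):
        med, _, _ = summarize_groups({"g": [1, 2, 3, 4]})["g"]
        assert med == 2.5

    def test_single_value(self):
        assert summarize_groups({"g": [3.3]})["g"] == (3.3, 3.3, 3.3)


class TestCompareGroups:
    def test_full_comparison_structure(self, rng):
        groups = {
            "a": (rng.standard_normal(10) + 1.0).tolist(),
            "b": rng.standard_normal(8).tolist(),
            "c": (rng.standard_normal(6) - 1.0).tolist(),
        }
        cmp = compare_groups(groups)
        pairs = {frozenset(p) for p, *_ in cmp.pairwise}
        assert pairs == {
            frozenset({"a", "b"}),
            frozenset({"a", "c"}),
            frozenset({"b", "c"}),
        }
        flags = benjamini_hochberg([p for _, _, p, _ in cmp.pairwise], q=0.05)
        assert flags == [rej for *_, rej in cmp.pairwise]
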