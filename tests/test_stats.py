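"""Rank tests, correlations and regression against hand and oracle values."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spdefmeth.exceptions import DegenerateDesignError, UndefinedCorrelationError
from spdefmeth.stats import (
    GroupedValues,
    concordance_r2,
    dunn_posthoc,
    kruskal_wallis,
    linear_fit,
    mann_whitney_u,
    spearman,
)


class TestMannWhitney:
    def test_no_overlap_gives_zero_u(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_interleaved_pairs(self):
        # pairs (a > b): only 3 > 2 -> U = 1
        assert mann_whitney_u([1, 3], [2, 4]).statistic == 1.0

    def test_identical_samples_symmetric_p(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value > 0.9

    def test_exact_p_matches_permutation_oracle(self):
        """Exact enumeration over all label assignments at small n."""
        a, b = [1.2, 3.4, 5.6], [2.3, 4.5, 6.7, 8.9]
        res = mann_whitney_u(a, b)
        pooled = a + b
        n_a = len(a)

        def u_stat(sample_a, sample_b):
            return sum(x > y for x in sample_a for y in sample_b)

        u_obs = min(u_stat(a, b), len(a) * len(b) - u_stat(a, b))
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            sa = [pooled[i] for i in idx]
            sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = min(u_stat(sa, sb), len(sa) * len(sb) - u_stat(sa, sb))
            total += 1
            if u <= u_obs:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        g = GroupedValues(["a", "b", "c"], [[1, 2], [3, 4], [5, 6]])
        # ranks 1..6: H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 4.571
        assert kruskal_wallis(g).statistic == pytest.approx(32 / 7, abs=1e-9)

    def test_two_group_reduction_matches_mwu_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        kw = kruskal_wallis(GroupedValues(["a", "b"], [a, b]))
        mw = mann_whitney_u(a, b)
        assert kw.p_value == pytest.approx(mw.p_value, rel=0.05)

    def test_all_ties_degenerate(self):
        g = GroupedValues(["a", "b"], [[2.0, 2.0, 2.0], [2.0, 2.0]])
        res = kruskal_wallis(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @given(
        data=st.lists(
            st.lists(
                st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 3)),
                min_size=3,
                max_size=8,
            ),
            min_size=2,
            max_size=4,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_invariance_under_monotone_transform(self, data):
        """H depends on the pooled data only through ranks."""
        g1 = GroupedValues([str(i) for i in range(len(data))], data)
        transformed = [list(np.exp(np.asarray(v) / 25.0)) for v in data]
        g2 = GroupedValues([str(i) for i in range(len(data))], transformed)
        h1, h2 = kruskal_wallis(g1).statistic, kruskal_wallis(g2).statistic
        assert h1 == pytest.approx(h2, rel=1e-9, abs=1e-9)


class TestTypeIError:
    def test_null_rejection_rates_at_alpha_05(self):
        """Empirical size of MWU and KW on identically distributed groups."""
        rng = np.random.default_rng(2024)
        n_sim = 10_000
        rej_mwu = rej_kw = 0
        data = rng.normal(0, 1, (n_sim, 30))
        for row in data:
            a, b, c = row[:10], row[10:20], row[20:]
            if sps.mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.05:
                rej_mwu += 1
            if sps.kruskal(a, b, c).pvalue < 0.05:
                rej_kw += 1
        assert 0.03 <= rej_mwu / n_sim <= 0.07
        assert 0.03 <= rej_kw / n_sim <= 0.07


class TestDunn:
    def _grouped(self, rng, deltas, n=20):
        return GroupedValues(
            [f"g{i}" for i in range(len(deltas))],
            [rng.normal(d, 1, n) for d in deltas],
        )

    def test_unadjusted_equals_raw_normal_p(self, rng):
        g = self._grouped(rng, [0, 0.5, 1.0])
        raw = dunn_posthoc(g, adjust="none")
        for comp in raw.comparisons:
            expected = 2 * sps.norm.sf(abs(comp.statistic))
            assert comp.p_adjusted == pytest.approx(expected)
            assert comp.p_adjusted == comp.p_value

    def test_bonferroni_dominates_raw(self, rng):
        g = self._grouped(rng, [0, 0.3, 0.6, 0.9])
        res = dunn_posthoc(g, adjust="bonferroni")
        for comp in res.comparisons:
            assert comp.p_adjusted >= comp.p_value
            assert comp.p_adjusted <= 1.0

    def test_separated_pair_significant(self, rng):
        g = self._grouped(rng, [0.0, 0.2, 5.0])
        res = dunn_posthoc(g)
        far = next(c for c in res.comparisons if c.pair == ("g0", "g2"))
        assert far.p_adjusted < 0.001

    def test_familywise_error_under_null(self):
        """With identical group distributions, the probability of any
        Bonferroni-adjusted pair falling below 0.05 stays near or below
        the nominal level."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            g = GroupedValues(
                ["a", "b", "c"], [rng.normal(0, 1, 50) for _ in range(3)]
            )
            res = dunn_posthoc(g)
            if any(c.p_adjusted < 0.05 for c in res.comparisons):
                hits += 1
        assert hits / n_sim <= 0.065

    def test_z_matches_hand_formula_with_ties(self):
        g = GroupedValues(["a", "b"], [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]])
        res = dunn_posthoc(g, adjust="none")
        pooled = np.array([1, 2, 2, 2, 3, 4], dtype=float)
        ranks = sps.rankdata(pooled)
        n = 6
        tie = (3**3 - 3) / (12 * (n - 1))
        var = n * (n + 1) / 12 - tie
        z = (ranks[:3].mean() - ranks[3:].mean()) / np.sqrt(var * (2 / 3))
        assert res.comparisons[0].statistic == pytest.approx(z)

    def test_singleton_group_warns(self, rng):
        g = GroupedValues(["a", "b"], [[1.0], list(rng.normal(0, 1, 5))])
        with pytest.warns(UserWarning, match="singleton"):
            dunn_posthoc(g)


class TestSpearman:
    def test_perfect_inversion(self):
        assert spearman([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).statistic == pytest.approx(0.8)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        xy=st.lists(
            st.tuples(st.floats(-100, 100, allow_nan=False),
                      st.floats(-100, 100, allow_nan=False)),
            min_size=3,
            max_size=30,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_equals_pearson_on_ranks(self, xy):
        x = [p[0] for p in xy]
        y = [p[1] for p in xy]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rho = spearman(x, y).statistic
        ref = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]
        assert rho == pytest.approx(ref, abs=1e-9)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(fit.r * fit.r, abs=1e-12)

    def test_perturbed_slope_within_ci(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = -x.copy()
        y[2] += 0.1
        fit = linear_fit(x, y)
        lo, hi = fit.ci95_slope
        assert lo <= -1.0 <= hi
        assert fit.r < 0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            linear_fit([1, 2], [1, 2])
        with pytest.raises(DegenerateDesignError):
            linear_fit([2, 2, 2], [1, 2, 3])


class TestConcordance:
    def test_identical_vectors(self):
        assert concordance_r2([1, 2, 3.5], [1, 2, 3.5]) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(5)
        assert concordance_r2(rng.normal(0, 1, 1000),
                              rng.normal(0, 1, 1000)) < 0.01

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            concordance_r2([1, 1, 1], [1, 2, 3])
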