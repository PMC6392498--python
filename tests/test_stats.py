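"""Statistical toolbox versus independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from stra8pipe.stats import (
    bh_fdr,
    binomial_enrichment,
    fisher_exact,
    hypergeom_overlap,
    mann_whitney,
    spearman_permutation,
)

# ---------------------------------------------------------------- oracles


def hypergeom_tail_oracle(N, K, n, k, upper):
    """Exact tail from combinatorial enumeration."""
    total = math.comb(N, n)
    support = range(k, min(K, n) + 1) if upper else range(max(0, K + n - N), k + 1)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in support) / total


def fisher_two_tailed_oracle(a, b, c, d):
    """Enumerate all 2x2 tables with the observed margins; sum P(table) <= P(obs)."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2

    def prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(N, c1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mann_whitney_oracle(x, y, alternative):
    """Exact permutation distribution of U over all group assignments."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p_g = np.mean(us >= u_obs - 1e-9)
    p_l = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return p_g
    if alternative == "less":
        return p_l
    return min(1.0, 2 * min(p_g, p_l))


# ---------------------------------------------------------------- hypergeometric


class TestHypergeomOverlap:
    def test_complete_overlap_exact_value(self):
        # C(5,5)C(5,0)/C(10,5) = 1/252
        res = hypergeom_overlap(10, 5, 5, 5)
        assert res.p_over == pytest.approx(1 / 252)

    def test_depletion_tail_exact_value(self):
        # N=4,K=2,n=2,k=0: p_under = C(2,0)C(2,2)/C(4,2) = 1/6
        res = hypergeom_overlap(4, 2, 2, 0)
        assert res.p_under == pytest.approx(1 / 6)

    def test_over_tail_monotone_in_universe_size(self):
        ps = [hypergeom_overlap(N, 20, 20, 20).p_over for N in (40, 100, 1000)]
        assert ps[0] > ps[1] > ps[2]

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            N = int(rng.integers(4, 40))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            res = hypergeom_overlap(N, K, n, k)
            assert res.p_over == pytest.approx(hypergeom_tail_oracle(N, K, n, k, True))
            assert res.p_under == pytest.approx(hypergeom_tail_oracle(N, K, n, k, False))

    def test_log_space_survives_extreme_values(self):
        # overlap far beyond what double-precision tails can represent
        res = hypergeom_overlap(20_000, 3000, 3000, 2500)
        assert res.p_over == 0.0  # underflows as a plain float
        assert np.isfinite(res.log10_p_over) and res.log10_p_over < -320

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)


# ---------------------------------------------------------------- Fisher


class TestFisherExact:
    def test_symmetric_table_is_null(self):
        res = fisher_exact([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_strong_association_closed_form_or(self):
        res = fisher_exact([[90, 10], [10, 90]])
        assert res.odds_ratio == pytest.approx(81.0)
        assert res.p < 1e-15
        assert res.ci_low < 81 < res.ci_high

    def test_small_table_matches_enumeration(self):
        res = fisher_exact([[2, 0], [0, 2]])
        assert res.p == pytest.approx(fisher_two_tailed_oracle(2, 0, 0, 2))
        assert res.p == pytest.approx(1 / 3)

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            res = fisher_exact([[a, b], [c, d]])
            assert res.p == pytest.approx(fisher_two_tailed_oracle(a, b, c, d), abs=1e-10)

    def test_zero_cell_haldane_flagged(self):
        res = fisher_exact([[5, 0], [2, 7]])
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))

    def test_agrees_with_one_tailed_hypergeometric(self, rng):
        """Fisher's one-sided p equals the hypergeometric over-representation tail."""
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            N, K, n = a + b + c + d, a + b, a + c
            if N == 0:
                continue
            _, p_one = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert hypergeom_overlap(N, K, n, a).p_over == pytest.approx(p_one, abs=1e-10)

    def test_published_style_counts_reconstruction(self):
        # counts reconstructed from printed fractions: 89% of 1518 bound DE genes up,
        # 32.4% of 3121 unbound DE genes up -> OR ~ 16.9, inside the printed CI
        res = fisher_exact([[1351, 167], [1010, 2111]])
        assert res.odds_ratio == pytest.approx(16.91, abs=0.01)
        # Woolf interval lands close to the printed (conditional-likelihood) CI
        assert res.ci_low == pytest.approx(14.3, abs=0.5)
        assert res.ci_high == pytest.approx(20.6, abs=0.5)


# ---------------------------------------------------------------- binomial enrichment


class TestBinomialEnrichment:
    def setup_method(self):
        self.background = {f"g{i}" for i in range(100)}

    def test_category_equal_to_background_is_null(self):
        target = {f"g{i}" for i in range(10)}
        (res,) = binomial_enrichment(target, {"all": set(self.background)}, self.background)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_perfect_enrichment_closed_form(self):
        cat = {f"g{i}" for i in range(10)}  # 10% of background
        target = set(cat)
        (res,) = binomial_enrichment(target, {"cat": cat}, self.background)
        assert res.fold_enrichment == pytest.approx(10.0)
        assert res.p_raw == pytest.approx(0.1**10, rel=1e-9)

    def test_bonferroni_multiplies_by_tested_categories(self):
        cat = {f"g{i}" for i in range(50)}
        cats = {f"c{j}": cat for j in range(5)}
        results = binomial_enrichment({"g0", "g1"}, cats, self.background)
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, 5 * r.p_raw))

    def test_null_targets_rarely_significant(self):
        background = {f"g{i}" for i in range(1000)}
        genes = sorted(background)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            cats = {f"c{j}": set(r.choice(genes, 50, replace=False)) for j in range(50)}
            target = set(r.choice(genes, 20, replace=False))
            results = binomial_enrichment(target, cats, background)
            if min(x.p_bonferroni for x in results) < 0.05:
                hits += 1
        assert hits <= 2  # >= 90% of seeds show no Bonferroni-significant category

    def test_set_difference_category(self):
        cycle = {f"g{i}" for i in range(30)}
        meiotic = {f"g{i}" for i in range(10)}
        (res,) = binomial_enrichment(
            {"g15", "g16", "g17"}, {"cycle_minus_meiotic": cycle - meiotic}, self.background
        )
        assert res.n_target_in_category == 3

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            binomial_enrichment(set(), {"c": set()}, set())


# ---------------------------------------------------------------- Mann-Whitney


class TestMannWhitney:
    def test_separated_samples_exact_tail(self):
        # all x below all y: P = 1/C(6,3) = 0.05 that y ranks above x by chance
        _, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_two_sided_unity(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle_with_ties(self, alternative, rng):
        for _ in range(20):
            nx, ny = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            x = rng.integers(0, 5, nx).tolist()  # small ints force ties
            y = rng.integers(0, 5, ny).tolist()
            _, p = mann_whitney(x, y, alternative=alternative)
            assert p == pytest.approx(mann_whitney_oracle(x, y, alternative), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        # 8 vs 8 uses the exact path; compare with scipy's corrected normal approx
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        _, p_exact = mann_whitney(x, y, alternative="two-sided")
        p_approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------- BH and permutation


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_fdr(p) == pytest.approx(q_ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSpearmanPermutation:
    def test_perfect_correlation_minimal_p(self):
        x = np.arange(20.0)
        rho, p = spearman_permutation(x, x, n_permutations=200, rng=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_null_p_values_not_inflated(self):
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            rho, p = spearman_permutation(r.normal(size=50), r.normal(size=50), 200, rng=seed)
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman_permutation([1, 1, 1], [1, 2, 3], 100, rng=0)
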