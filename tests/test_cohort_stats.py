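"""Permutation test, BH FDR and Pearson correlation against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmeta.cohort_stats import (
    Cohort,
    InsufficientDataError,
    UndefinedCorrelationError,
    bh_fdr,
    cohort_gene_stats,
    mirna_mrna_correlation,
    permutation_de_test,
)
from mirmeta.simulate import CohortSimConfig, simulate_cohorts


def exhaustive_perm_oracle(tumor, normal):
    """Enumerate every label assignment; exact two-sided tail fraction."""
    pooled = list(tumor) + list(normal)
    n1 = len(tumor)
    obs = np.mean(tumor) - np.mean(normal)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp1 = [pooled[i] for i in idx]
        grp2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        d = np.mean(grp1) - np.mean(grp2)
        total += 1
        if abs(d) >= abs(obs) - 1e-12:
            hits += 1
    return hits / total


def bh_oracle(p):
    """Literal step-up definition: q(i) = min_{j>=i} min(1, p(j)*n/j)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, min(1.0, sorted_p[i] * n / (i + 1)))
        q[i] = running
    out = np.empty(n)
    out[order] = q
    return out


class TestPermutationTest:
    def test_degenerate_constant_data(self):
        p, lf = permutation_de_test([5, 5, 5], [5, 5, 5])
        assert p == 1.0 and lf == 0.0

    def test_two_vs_two_exact(self):
        p, lf = permutation_de_test([3, 4], [1, 2])
        assert p == pytest.approx(1 / 3)
        assert lf == 2.0

    def test_three_vs_three_exact(self):
        p, lf = permutation_de_test([10, 11, 12], [1, 2, 3])
        assert p == pytest.approx(0.1)
        assert lf == 9.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 4), (5, 5), (6, 6), (3, 5)])
    def test_exhaustive_equals_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(10):
            t = rng.normal(1.0, 1.0, n1)
            n = rng.normal(0.0, 1.0, n2)
            p, _ = permutation_de_test(t, n)
            assert p == pytest.approx(exhaustive_perm_oracle(t, n))

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0.8, 1.0, 5)
        n = rng.normal(0.0, 1.0, 5)
        exact, _ = permutation_de_test(t, n)  # C(10,5)=252 -> exhaustive
        mc, _ = permutation_de_test(
            t, n, n_perm=100_000, seed=3, exhaustive_limit=1
        )
        assert abs(mc - exact) < 0.01

    def test_monte_carlo_add_one_never_zero(self):
        t = [100.0, 101.0, 102.0, 103.0, 104.0, 105.0, 106.0, 107.0]
        n = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        p, _ = permutation_de_test(t, n, n_perm=200, seed=0, exhaustive_limit=1)
        assert p == pytest.approx(1 / 201)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            permutation_de_test([1.0], [2.0, 3.0])

    def test_deterministic_given_seed(self):
        t = list(range(12))
        n = list(range(5, 17))
        p1, _ = permutation_de_test(t, n, n_perm=500, seed=9, exhaustive_limit=1)
        p2, _ = permutation_de_test(t, n, n_perm=500, seed=9, exhaustive_limit=1)
        assert p1 == p2


class TestBhFdr:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(1e-8, 1.0, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-10, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_oracle_property(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_order_invariance(self):
        p = [0.04, 0.001, 0.9, 0.2, 0.049]
        perm = [2, 0, 4, 1, 3]
        direct = bh_fdr(p)
        shuffled = bh_fdr([p[i] for i in perm])
        np.testing.assert_allclose([direct[i] for i in perm], shuffled)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p = mirna_mrna_correlation([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5])
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(1e-300)  # floored, never 0

    def test_df2_closed_form(self):
        """r=0.6, n=4: p from the df=2 closed-form t CDF is 0.400."""
        r, p = mirna_mrna_correlation([1, 2, 3, 4], [2, 1, 4, 3], min_matched=4)
        assert r == pytest.approx(0.6)
        t = 0.6 * math.sqrt(2) / math.sqrt(1 - 0.36)
        closed = 2 * (1 - (0.5 + t / (2 * math.sqrt(t * t + 2))))
        assert p == pytest.approx(closed, rel=1e-9)
        assert p == pytest.approx(0.4, abs=1e-12)

    def test_absent_below_min_matched(self):
        assert mirna_mrna_correlation([1, 2, 3], [1, 2, 3]) == (None, None)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            mirna_mrna_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_null_p_uniform(self):
        """Correlation p-values under independence are Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(2000):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            _, p = mirna_mrna_correlation(x, y)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestCohortGeneStats:
    def test_planted_target_has_minimum_fdr(self):
        cfg = CohortSimConfig(
            name="c", n_genes=50, n_planted_targets=1, n_tumor=10, n_normal=10,
            n_matched=8, mirna_tumor_shift=4.0, target_slope=-3.0,
            noise_sd=0.3, frac_decoy_down=0.0, frac_decoy_corr=0.0, seed=3,
        )
        cohorts, truth = simulate_cohorts([cfg])
        stats = cohort_gene_stats(cohorts[0], n_perm=999, seed=0)
        planted = next(iter(truth.planted_target_ids))
        by_gene = {s.gene_id: s for s in stats}
        assert by_gene[planted].fdr == min(s.fdr for s in stats)
        assert by_gene[planted].log2fold < 0
        assert by_gene[planted].r < -0.6

    def test_cohort_without_mirna_leaves_correlation_absent(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(8)]
        cohort = Cohort(
            name="mrna_only",
            mirna=None,
            mrna=pd.DataFrame(
                rng.normal(size=(5, 8)),
                index=[f"g{i}" for i in range(5)],
                columns=samples,
            ),
            sample_class=pd.Series(
                ["tumor"] * 4 + ["normal"] * 4, index=samples
            ),
            matched=frozenset(),
        )
        stats = cohort_gene_stats(cohort, n_perm=199, seed=0)
        assert all(s.r is None and s.p_r is None for s in stats)
        assert all(np.isfinite(s.p_tn) and np.isfinite(s.log2fold) for s in stats)

    def test_gene_with_missing_values_dropped(self, caplog):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(8)]
        m = pd.DataFrame(
            rng.normal(size=(3, 8)),
            index=["g0", "g1", "g2"],
            columns=samples,
        )
        m.loc["g1", "s2"] = np.nan
        cohort = Cohort(
            name="c",
            mirna=None,
            mrna=m,
            sample_class=pd.Series(["tumor"] * 4 + ["normal"] * 4, index=samples),
        )
        stats = cohort_gene_stats(cohort, n_perm=99, seed=0)
        assert [s.gene_id for s in stats] == ["g0", "g2"]
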