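"""GLS/PGLS, the lambda profile, Welch t, pooling, slope comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enamelfractal import (
    ComparativeDataset,
    GroupStats,
    PhyloCovariance,
    compare_slopes,
    distribution_checks,
    gls_fit,
    lambda_signal,
    lambda_transform,
    phylo_covariance,
    pooled_from_species,
    profile_lambda,
    simulate_traits,
    simulate_tree,
    summarize_species,
    table1_fixture,
    welch_t,
)
from enamelfractal.trace_io import SpecimenRecord


def random_spd_cov(rng, n):
    A = rng.normal(size=(n, n))
    V = A @ A.T + n * np.eye(n)
    return PhyloCovariance([f"s{i}" for i in range(n)], V)


def random_dataset(rng, n):
    x = rng.uniform(1, 10, size=n)
    y = 1.4 - 0.02 * x + rng.normal(0, 0.05, size=n)
    return ComparativeDataset([f"s{i}" for i in range(n)], x, y)


class TestLambdaTransform:
    def test_identity_at_one_and_diagonal_at_zero(self, rng):
        V = random_spd_cov(rng, 6)
        assert np.allclose(lambda_transform(V, 1.0).V, V.V)
        V0 = lambda_transform(V, 0.0).V
        assert np.allclose(V0, np.diag(np.diag(V.V)))

    def test_elementwise_oracle_at_half(self, rng):
        V = random_spd_cov(rng, 5)
        Vl = lambda_transform(V, 0.5).V
        for i in range(5):
            for j in range(5):
                expect = V.V[i, j] if i == j else 0.5 * V.V[i, j]
                assert Vl[i, j] == pytest.approx(expect, abs=1e-15)

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            lambda_transform(random_spd_cov(rng, 4), 1.5)


class TestGlsFit:
    def test_identity_covariance_equals_ols(self, rng):
        for _ in range(5):
            n = int(rng.integers(8, 30))
            data = random_dataset(rng, n)
            V = PhyloCovariance(data.taxa, np.eye(n))
            fit = gls_fit(data, V)
            lr = stats.linregress(data.x, data.y)
            assert fit.slope == pytest.approx(lr.slope, abs=1e-10)
            assert fit.intercept == pytest.approx(lr.intercept, abs=1e-10)
            assert fit.se_slope == pytest.approx(lr.stderr, abs=1e-10)
            assert fit.p_slope == pytest.approx(lr.pvalue, abs=1e-10)
            assert fit.r2_multiple == pytest.approx(lr.rvalue**2, abs=1e-10)

    def test_diagonal_covariance_matches_weighted_oracle(self):
        # 4-point hand dataset, V = diag(1,1,1,4): weighted LS with w = 1/Vii
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.7])
        data = ComparativeDataset(["a", "b", "c", "d"], x, y)
        V = PhyloCovariance(data.taxa, np.diag([1.0, 1.0, 1.0, 4.0]))
        fit = gls_fit(data, V)
        w = 1.0 / np.array([1.0, 1.0, 1.0, 4.0])
        W = np.diag(w)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)

    def test_r2_adjusted_below_multiple(self, rng):
        data = random_dataset(rng, 12)
        fit = gls_fit(data, PhyloCovariance(data.taxa, np.eye(12)))
        assert fit.r2_adjusted <= fit.r2_multiple

    def test_too_few_species_rejected(self):
        data = ComparativeDataset(["a", "b"], [1, 2], [1, 2])
        with pytest.raises(ValueError):
            gls_fit(data, PhyloCovariance(["a", "b"], np.eye(2)))


class TestProfileLambda:
    def test_bm_simulation_recovers_high_lambda(self):
        tree = simulate_tree(64, seed=1)
        V = phylo_covariance(tree)
        lams = []
        for rep in range(25):
            data = simulate_traits(tree, lam=1.0, sigma2=0.05, seed=100 + rep)
            fit = profile_lambda(data, V)
            lams.append(fit.lambda_hat)
            assert 0.0 <= fit.lambda_hat <= 1.0
        assert np.median(lams) >= 0.85

    def test_permuted_tips_destroy_signal(self):
        tree = simulate_tree(64, seed=1)
        V = phylo_covariance(tree)
        rng = np.random.default_rng(42)
        lams = []
        for rep in range(25):
            data = simulate_traits(tree, lam=1.0, sigma2=0.05, seed=300 + rep)
            perm = rng.permutation(len(data.taxa))
            shuffled = ComparativeDataset(data.taxa, data.x, data.y[perm])
            lams.append(profile_lambda(shuffled, V).lambda_hat)
        assert np.median(lams) <= 0.1

    def test_boundary_ci_endpoints_reported_absent(self):
        tree = simulate_tree(32, seed=2)
        V = phylo_covariance(tree)
        data = simulate_traits(tree, lam=0.0, sigma2=0.01, seed=9)
        fit = profile_lambda(data, V)
        assert fit.lambda_hat == pytest.approx(0.0, abs=0.05)
        assert fit.lambda_ci[0] is None  # hugs the 0 boundary

    def test_loglik_dominates_endpoints(self):
        tree = simulate_tree(24, seed=5)
        V = phylo_covariance(tree)
        for rep in range(5):
            data = simulate_traits(tree, lam=0.5, sigma2=0.02, seed=rep)
            fit = profile_lambda(data, V)
            for lam_end in (0.0, 1.0):
                end = gls_fit(data, V, lam=lam_end)
                assert fit.loglik >= end.loglik - 1e-6


class TestLambdaSignal:
    def test_constant_trait_unidentifiable(self):
        tree = simulate_tree(10, seed=0)
        V = phylo_covariance(tree)
        with pytest.warns(UserWarning, match="unidentifiable"):
            lam, ci = lambda_signal({t: 1.0 for t in V.taxa}, V)
        assert lam == 0.0

    def test_bm_trait_signals_near_one(self):
        tree = simulate_tree(64, seed=3)
        V = phylo_covariance(tree)
        lams = []
        for rep in range(10):
            data = simulate_traits(tree, lam=1.0, sigma2=0.05, seed=500 + rep)
            lam, _ = lambda_signal(dict(zip(data.taxa, data.y)), V)
            lams.append(lam)
        assert np.median(lams) >= 0.85


class TestWelch:
    def test_identical_groups(self):
        g = GroupStats("a", 10, 1.5, 0.3)
        t, df, p = welch_t(g, GroupStats("b", 10, 1.5, 0.3))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        a = GroupStats("a", 5, 1.0, 1.0)
        b = GroupStats("b", 7, 2.0, 1.0)
        t, df, p = welch_t(a, b)
        se = np.sqrt(1 / 5 + 1 / 7)
        assert t == pytest.approx(-1.0 / se, abs=1e-12)
        df_oracle = (1 / 5 + 1 / 7) ** 2 / ((1 / 5) ** 2 / 4 + (1 / 7) ** 2 / 6)
        assert df == pytest.approx(df_oracle, abs=1e-12)
        # independent implementation cross-check
        t2, p2 = stats.ttest_ind_from_stats(
            1.0, 1.0, 5, 2.0, 1.0, 7, equal_var=False
        )
        assert t == pytest.approx(t2, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-12)

    @given(
        st.floats(0.5, 3), st.floats(0.5, 3),
        st.floats(0.1, 2), st.floats(0.1, 2),
        st.integers(3, 50), st.integers(3, 50),
    )
    @settings(max_examples=30, deadline=None)
    def test_antisymmetric_under_exchange(self, m1, m2, v1, v2, n1, n2):
        a, b = GroupStats("a", n1, m1, v1), GroupStats("b", n2, m2, v2)
        t_ab, df_ab, p_ab = welch_t(a, b)
        t_ba, df_ba, p_ba = welch_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert df_ab == pytest.approx(df_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t(GroupStats("a", 5, 1, 0.0), GroupStats("b", 5, 1, 1.0))


class TestPooledFromSpecies:
    def test_single_species_passthrough(self):
        recs = [
            SpecimenRecord(f"s{i}", "X", "Equini", "P3", D=d)
            for i, d in enumerate([1.3, 1.4, 1.5])
        ]
        (summary,) = summarize_species(recs)
        pooled = pooled_from_species([summary], "Equini")
        assert pooled.n == 3
        assert pooled.mean == pytest.approx(1.4)
        assert pooled.var == pytest.approx(np.var([1.3, 1.4, 1.5], ddof=1))

    def test_hand_decomposition_two_species(self):
        recs = [
            SpecimenRecord("a", "X", "Equini", "P3", D=1.0),
            SpecimenRecord("b", "X", "Equini", "P3", D=1.0),
            SpecimenRecord("c", "Y", "Equini", "P3", D=3.0),
            SpecimenRecord("d", "Y", "Equini", "P3", D=3.0),
        ]
        pooled = pooled_from_species(summarize_species(recs), "Equini")
        assert pooled.mean == pytest.approx(2.0)
        assert pooled.var == pytest.approx(4.0 / 3.0)

    def test_equini_fixture_pools_to_published_mean(self):
        pooled = pooled_from_species(table1_fixture(), "Equini")
        assert round(pooled.mean, 3) == 1.359

    def test_exact_against_specimen_level_cohort(self, rng):
        recs = []
        for sp in range(8):
            for k in range(int(rng.integers(1, 6))):
                recs.append(
                    SpecimenRecord(
                        f"s{sp}_{k}", f"sp{sp}", "Hipparionini", "P3",
                        D=float(rng.normal(1.43, 0.06)),
                    )
                )
        pooled = pooled_from_species(summarize_species(recs), "Hipparionini")
        direct = np.array([r.D for r in recs])
        assert pooled.n == len(direct)
        assert pooled.mean == pytest.approx(direct.mean(), abs=1e-12)
        assert pooled.var == pytest.approx(direct.var(ddof=1), abs=1e-12)


class TestCompareSlopes:
    def test_identical_fits_give_zero(self, rng):
        data = random_dataset(rng, 10)
        fit = gls_fit(data, PhyloCovariance(data.taxa, np.eye(10)))
        t, df, p = compare_slopes(fit, fit)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_case_formula_oracle(self, rng):
        d1 = random_dataset(rng, 10)
        fit1 = gls_fit(d1, PhyloCovariance(d1.taxa, np.eye(10)))
        fit2 = gls_fit(d1, PhyloCovariance(d1.taxa, np.eye(10)))
        fit1.slope, fit1.se_slope = 1.0, 0.5
        fit2.slope, fit2.se_slope = 0.0, 0.5
        t, df, p = compare_slopes(fit1, fit2)
        assert t == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert df == 16
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(2.0), 16), abs=1e-15)


class TestDistributionChecks:
    def test_degenerate_group_flagged(self):
        report = distribution_checks({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4]})
        assert report["shapiro"]["a"]["degenerate"] is True
        assert report["bartlett"] is None  # only one usable group

    def test_bartlett_detects_variance_ratio_nine(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(0, 3, size=30)
        report = distribution_checks({"a": a, "b": b})
        assert report["bartlett"]["p"] < 0.05
        stat, p = stats.bartlett(a, b)
        assert report["bartlett"]["statistic"] == pytest.approx(stat)

    def test_normal_samples_mostly_pass_shapiro(self, rng):
        rejections = 0
        for _ in range(100):
            report = distribution_checks({"g": rng.normal(size=50)})
            if report["shapiro"]["g"]["p"] < 0.05:
                rejections += 1
        assert rejections < 20  # far from systematic rejection
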