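"""Tests for the inverse-normal transform, weights, and the SKAT family.

Independent oracles used here: dense quadratic-form evaluation, chi-square
closed forms, Monte-Carlo mixture tails, permutation of residuals, and the
classical linear-model score test.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import rareqtl as rq
from rareqtl import skat as sk
from rareqtl.errors import DegenerateInputError
from rareqtl.results import STATUS_DEGENERATE
from tests.test_simdata import make_matrix


class TestInverseNormalTransform:
    def test_three_point_blom_scores(self):
        y = sk.inverse_normal_transform(np.array([10, 20, 30]))
        # Blom positions (1-3/8)/3.25, (2-3/8)/3.25, (3-3/8)/3.25
        expected = stats.norm.ppf([0.625 / 3.25, 1.625 / 3.25, 2.625 / 3.25])
        assert np.allclose(y, expected, atol=1e-10)
        assert y[1] == pytest.approx(0.0, abs=1e-12)
        assert y[2] == pytest.approx(0.86942, abs=1e-4)

    def test_ties_get_equal_scores(self):
        y = sk.inverse_normal_transform(np.array([5, 5, 9]))
        assert y[0] == y[1]

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            sk.inverse_normal_transform(np.array([7, 7, 7]))

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 50, 12)
        if np.ptp(t) == 0:
            t[0] += 1
        perm = rng.permutation(12)
        y = sk.inverse_normal_transform(t)
        assert np.allclose(sk.inverse_normal_transform(t[perm]), y[perm])

    def test_mean_near_zero_without_ties(self, rng):
        t = rng.permutation(200)
        y = sk.inverse_normal_transform(t)
        assert abs(y.mean()) < 1e-6


class TestBetaWeights:
    def test_reference_values(self):
        w = sk.beta_weights(np.array([0.0, 0.005]), 1, 25).weights
        assert w[0] == pytest.approx(25.0, abs=1e-12)
        assert w[1] == pytest.approx(25 * 0.995**24, rel=1e-10)  # ~22.17
        assert w[1] == pytest.approx(22.17, abs=0.01)

    def test_uniform_when_flat(self):
        w = sk.beta_weights(np.array([0.0, 0.2, 0.5]), 1, 1).weights
        assert np.allclose(w, 1.0)

    def test_invalid_maf(self):
        with pytest.raises(ValueError):
            sk.beta_weights(np.array([-0.1]), 1, 25)


class TestNullModel:
    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(size=40)
        null = sk.fit_null_linear(y)
        assert np.allclose(null.residuals, y - y.mean())
        assert null.sigma2 == pytest.approx(np.var(y, ddof=1), rel=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        n, k = 50, 3
        C = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y, C=C)
        assert np.all(np.abs(null.design.T @ null.residuals) < 1e-8)

    def test_perfect_fit_warns(self, rng):
        C = rng.normal(size=30)
        y = 2.0 + 3.0 * C
        with pytest.warns(UserWarning, match="degenerate"):
            sk.fit_null_linear(y, C=C)


class TestSkatStatistic:
    def test_matches_dense_quadratic_form(self, rng):
        """Q agrees with an independently coded r' K r to 1e-10 relative."""
        for _ in range(20):
            n = int(rng.integers(6, 11))
            J = int(rng.integers(1, 4))
            d = rng.integers(0, 3, size=(n, J)).astype(float)
            if np.all(np.ptp(d, axis=0) == 0):
                d[0, 0] = 1.0
            G = make_matrix(d)
            y = rng.normal(size=n)
            null = sk.fit_null_linear(y)
            w = rng.random(J) + 0.1
            comp = sk.skat_statistic(null, G, w)
            K = d @ np.diag(w**2) @ d.T  # dense kernel, squared weights
            r = y - y.mean()
            q_dense = float(r @ K @ r)
            assert comp.Q == pytest.approx(q_dense, rel=1e-10)
            assert comp.Q >= 0

    def test_single_variant_squared_score(self, rng):
        n = 12
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y)
        comp = sk.skat_statistic(null, G, np.array([1.0]))
        r = y - y.mean()
        assert comp.Q == pytest.approx(float(r @ d[:, 0]) ** 2, rel=1e-12)

    def test_literal_convention_unsquared(self, rng):
        n, J = 15, 3
        d = rng.integers(0, 3, size=(n, J)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y)
        w = np.array([2.0, 3.0, 4.0])
        comp = sk.skat_statistic(null, G, w, weight_convention="literal")
        r = y - y.mean()
        assert comp.Q == pytest.approx(float(r @ (d @ np.diag(w) @ d.T) @ r), rel=1e-10)

    def test_all_zero_weights_rejected(self, rng):
        G = make_matrix(rng.integers(0, 3, size=(10, 2)).astype(float))
        null = sk.fit_null_linear(rng.normal(size=10))
        with pytest.raises(DegenerateInputError):
            sk.skat_statistic(null, G, np.zeros(2))


class TestQuadformPvalue:
    def test_chi2_closed_forms(self):
        assert rq.quadform_pvalue(3.841459, [1.0]) == pytest.approx(0.05, abs=1e-5)
        assert rq.quadform_pvalue(5.991465, [1.0, 1.0]) == pytest.approx(0.05, abs=1e-5)

    def test_matches_monte_carlo_tail(self):
        lam = np.array([2.0, 1.0, 0.5])
        q = 4.0
        rng = np.random.default_rng(77)
        draws = rng.chisquare(1, size=(10**6, 3)) @ lam
        p_mc = float(np.mean(draws >= q))
        se = np.sqrt(p_mc * (1 - p_mc) / 10**6)
        assert abs(rq.quadform_pvalue(q, lam) - p_mc) < 3 * se

    def test_monotone_decreasing_in_q(self):
        lam = [1.7, 0.9, 0.4, 0.2]
        qs = np.linspace(0.5, 25, 12)
        ps = [rq.quadform_pvalue(q, lam) for q in qs]
        assert np.all(np.diff(ps) < 0)

    def test_davies_vs_liu_sanity_band(self, rng):
        """|p_davies - p_liu| < 0.02 whenever p_davies is in [0.01, 0.5]."""
        checked = 0
        for _ in range(40):
            m = int(rng.integers(2, 21))
            lam = rng.random(m) * 2 + 0.05
            q = float(np.sum(lam) * rng.uniform(0.8, 3.0))
            pd = rq.quadform_pvalue(q, lam, method="davies")
            pl = rq.quadform_pvalue(q, lam, method="liu")
            if 0.01 <= pd <= 0.5:
                checked += 1
                assert abs(pd - pl) < 0.02
        assert checked > 10

    def test_vectorized_grid_agrees_with_oscillatory_quadrature(self, rng):
        # two independent CF-inversion routes must coincide
        lam = np.sort(rng.random(20) * 3 + 0.01)[::-1]
        qs = np.linspace(1.0, 80.0, 15)
        grid = sk._imhof_sf_grid(qs, lam)
        assert grid is not None
        for q, pg in zip(qs, grid):
            assert pg == pytest.approx(sk._imhof_sf_osc(float(q), lam), abs=2e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rq.quadform_pvalue(1.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            rq.quadform_pvalue(-1.0, [1.0])


class TestSkatFamily:
    def test_single_variant_matches_score_test(self, rng):
        """J=1: SKAT p equals the two-sided linear-model score-test p."""
        n = 60
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n) + 0.3 * d[:, 0]
        null = sk.fit_null_linear(y)
        res = sk.skat_test(null, G, np.array([1.0]))
        r = y - y.mean()
        x = d[:, 0]
        xc = x - x.mean()
        z = float(r @ x) / np.sqrt(null.sigma2 * float(xc @ xc))
        p_score = 2 * stats.norm.sf(abs(z))
        assert res.p_value == pytest.approx(p_score, abs=1e-4)

    def test_burden_equals_skat_single_variant(self, rng):
        n = 40
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        p_skat = sk.skat_test(null, G, W).p_value
        p_burden = sk.burden_test(null, G, W).p_value
        assert p_burden == pytest.approx(p_skat, abs=1e-6)

    def test_j1_concordance_all_three(self, rng):
        """J=1: SKAT, SKAT-Burden and SKAT-O agree within 1e-3."""
        n = 50
        d = rng.integers(0, 3, size=(n, 1)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        ps = [
            sk.skat_test(null, G, W).p_value,
            sk.burden_test(null, G, W).p_value,
            sk.skato_test(null, G, W).p_value,
        ]
        assert max(ps) - min(ps) < 1e-3

    def test_burden_matches_linear_score_test(self, small_region, rng):
        G = small_region
        y = rng.normal(size=G.n_subjects)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        res = sk.burden_test(null, G, W)
        b = G.dosages @ W.weights
        bc = b - b.mean()
        r = y - y.mean()
        z = float(r @ b) / np.sqrt(null.sigma2 * float(bc @ bc))
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-4)

    def test_skat_permutation_oracle(self, rng):
        """Null data, n=30: Davies p within MC error of a permutation p."""
        n, J = 30, 8
        d = rng.integers(0, 3, size=(n, J)).astype(float)
        G = make_matrix(d)
        y = rng.normal(size=n)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        res = sk.skat_test(null, G, W)
        Z = G.dosages * W.weights
        K = Z @ Z.T
        r = null.residuals
        q_obs = float(r @ K @ r)
        nperm = 10_000
        qs = np.empty(nperm)
        for i in range(nperm):
            rp = rng.permutation(r)
            qs[i] = rp @ K @ rp
        p_perm = float(np.mean(qs >= q_obs))
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / nperm)
        assert abs(res.p_value - p_perm) < max(3 * se, 0.02)

    def test_affine_invariance(self, small_region, rng):
        G = small_region
        y = rng.normal(size=G.n_subjects)
        W = sk.beta_weights(G.maf_sample)
        p1 = sk.skat_test(sk.fit_null_linear(y), G, W).p_value
        p2 = sk.skat_test(sk.fit_null_linear(3.0 + 2.5 * y), G, W).p_value
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_weight_scale_invariance(self, small_region, rng):
        G = small_region
        y = rng.normal(size=G.n_subjects)
        null = sk.fit_null_linear(y)
        w = sk.beta_weights(G.maf_sample).weights
        for test in (sk.skat_test, sk.burden_test, sk.skato_test):
            p1 = test(null, G, w).p_value
            p2 = test(null, G, 7.3 * w).p_value
            assert p1 == pytest.approx(p2, abs=1e-6)

    def test_burden_orthogonal_residuals_p_one(self, rng):
        # make the outcome orthogonal to the weighted burden by construction
        n = 20
        d = rng.integers(0, 3, size=(n, 2)).astype(float)
        G = make_matrix(d)
        W = sk.beta_weights(G.maf_sample)
        b = d @ W.weights
        bc = b - b.mean()
        y = rng.normal(size=n)
        y = y - (y @ bc) / (bc @ bc) * bc  # residuals now orthogonal to b
        null = sk.fit_null_linear(y)
        res = sk.burden_test(null, G, W)
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_no_variation(self):
        G = make_matrix(np.zeros((10, 3)))
        y = np.arange(10.0)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        assert sk.skat_test(null, G, W).status == STATUS_DEGENERATE
        assert sk.burden_test(null, G, W).status == STATUS_DEGENERATE
        assert sk.skato_test(null, G, W).status == STATUS_DEGENERATE


class TestSkatO:
    def test_rho_zero_equals_skat(self, small_region, rng):
        G = small_region
        y = rng.normal(size=G.n_subjects)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        p = sk.skato_test(null, G, W, rho_grid=[0.0]).p_value
        assert p == pytest.approx(sk.skat_test(null, G, W).p_value, abs=1e-6)

    def test_rho_one_equals_burden(self, small_region, rng):
        G = small_region
        y = rng.normal(size=G.n_subjects)
        null = sk.fit_null_linear(y)
        W = sk.beta_weights(G.maf_sample)
        p = sk.skato_test(null, G, W, rho_grid=[1.0]).p_value
        assert p == pytest.approx(sk.burden_test(null, G, W).p_value, abs=1e-6)

    def test_min_p_combination_bounds(self, small_region, rng):
        """min_rho p_rho <= p_SKATO <= |grid| * min_rho p_rho (within tol)."""
        G = small_region
        W = sk.beta_weights(G.maf_sample)
        grid = sk.DEFAULT_RHO_GRID
        for _ in range(10):
            y = rng.normal(size=G.n_subjects) + 0.2 * G.dosages.sum(1)
            null = sk.fit_null_linear(y)
            res = sk.skato_test(null, G, W)
            t_min = res.statistic  # reported statistic is min per-rho p
            assert t_min - 1e-4 <= res.p_value <= min(1.0, len(grid) * t_min) + 1e-4

    def test_null_calibration_skat_family(self):
        """y ~ N(0,1) independent of G: no type-I inflation at the 5% level.

        2000 replicates against a fixed n=100 genotype matrix.  The burden
        test (a single-df score test) is expected inside the two-sided 95%
        binomial band; SKAT and SKAT-O are additionally allowed to run
        conservative, which they genuinely are at n=100 with ~50 variants:
        Q and sigma2-hat share the same residuals, an F-type coupling the
        asymptotic chi-square mixture ignores, so the variance-component
        tests under-reject in small samples.
        """
        rng = np.random.default_rng(2024)
        freqs = rq.simulate_site_frequencies(58, seed=31)
        G = rq.filter_common(rq.sample_genotypes(freqs, 100, seed=32))
        W = sk.beta_weights(G.maf_sample)
        reps = 2000
        rej = {"SKAT": 0, "SKAT-O": 0, "SKAT-Burden": 0}
        for _ in range(reps):
            y = rng.normal(size=100)
            null = sk.fit_null_linear(y)
            if sk.skat_test(null, G, W).p_value <= 0.05:
                rej["SKAT"] += 1
            if sk.skato_test(null, G, W).p_value <= 0.05:
                rej["SKAT-O"] += 1
            if sk.burden_test(null, G, W).p_value <= 0.05:
                rej["SKAT-Burden"] += 1
        rates = {m: c / reps for m, c in rej.items()}
        assert 0.040 <= rates["SKAT-Burden"] <= 0.060, rates
        for m in ("SKAT", "SKAT-O"):
            assert 0.010 <= rates[m] <= 0.065, rates
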