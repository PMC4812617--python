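"""Ridge mixed-model tests against independent dense oracles.

The REML criterion is checked against an explicit error-contrast
likelihood (orthonormal basis of the complement of the intercept), and
the MME solver against a brute-force assembly of Henderson's full
(1+2p)-dimensional coefficient matrix.
"""

import numpy as np
import pytest
from scipy import linalg, stats

from hybridblup import (
    VarianceComponents,
    predict_gca,
    predict_hybrids,
    reml_fit,
    restricted_log_likelihood,
    solve_mme,
)
from hybridblup.model import predict_from_design
from hybridblup.predictors import build_design


def random_instance(rng, n, p_f, p_m):
    F = rng.normal(size=(n, p_f))
    M = rng.normal(size=(n, p_m))
    y = rng.normal(size=n) * 2 + 1.5
    return F, M, y


def contrast_loglik(F, M, y, vc):
    """Brute-force REML value: density of A'y for an orthonormal basis A
    of the orthogonal complement of the intercept column."""
    n = len(y)
    A = linalg.null_space(np.ones((1, n)))  # n x (n-1), orthonormal
    V = vc.sigma2_f * F @ F.T + vc.sigma2_m * M @ M.T + vc.sigma2_e * np.eye(n)
    return stats.multivariate_normal.logpdf(A.T @ y, mean=np.zeros(n - 1), cov=A.T @ V @ A)


def dense_mme_solution(F, M, y, vc):
    """Explicit Henderson system: [X Z] blocks with ridge penalties."""
    n, p_f = F.shape
    p_m = M.shape[1]
    W = np.hstack([np.ones((n, 1)), F, M])
    C = W.T @ W
    lam = np.concatenate([
        [0.0],
        np.full(p_f, vc.sigma2_e / vc.sigma2_f),
        np.full(p_m, vc.sigma2_e / vc.sigma2_m),
    ])
    C = C + np.diag(lam)
    sol = np.linalg.solve(C, W.T @ y)
    return sol[0], sol[1:1 + p_f], sol[1 + p_f:]


class TestRestrictedLogLikelihood:
    def test_matches_contrast_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            F, M, y = random_instance(rng, n, int(rng.integers(1, 4)), int(rng.integers(1, 4)))
            vc = VarianceComponents(*rng.uniform(0.2, 2.0, size=3))
            got = restricted_log_likelihood((F, M), y, vc)
            want = contrast_loglik(F, M, y, vc)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_intercept_only_maximized_at_sample_variance(self, rng):
        y = rng.normal(size=9)
        F = M = np.zeros((9, 0))
        s2_hat = np.var(y, ddof=1)
        ll_opt = restricted_log_likelihood((F, M), y, VarianceComponents(0, 0, s2_hat))
        for s2 in [0.3 * s2_hat, 0.7 * s2_hat, 1.4 * s2_hat, 3.0 * s2_hat]:
            assert restricted_log_likelihood((F, M), y, VarianceComponents(0, 0, s2)) < ll_opt

    def test_gaussian_scaling_identity(self, rng):
        n = 8
        F, M, y = random_instance(rng, n, 3, 2)
        vc = VarianceComponents(0.7, 1.1, 0.9)
        c = 2.5
        vc_scaled = VarianceComponents(0.7 * c**2, 1.1 * c**2, 0.9 * c**2)
        ll = restricted_log_likelihood((F, M), y, vc)
        ll_scaled = restricted_log_likelihood((F, M), c * y, vc_scaled)
        assert ll_scaled == pytest.approx(ll - (n - 1) * np.log(c), rel=1e-10)


class TestRemlFit:
    def test_no_predictors_gives_sample_variance(self, rng):
        y = rng.normal(size=15)
        vc = reml_fit((np.zeros((15, 0)), np.zeros((15, 0))), y)
        assert vc.sigma2_e == pytest.approx(np.var(y, ddof=1))
        assert vc.sigma2_f == 0.0 and vc.sigma2_m == 0.0

    def test_optimum_beats_neighbourhood(self, rng):
        """The returned components (locally) maximize the restricted
        likelihood: nudging each ratio degrades the criterion."""
        F, M, y = random_instance(rng, 30, 8, 8)
        y = y + F @ rng.normal(0, 0.5, 8) + M @ rng.normal(0, 0.5, 8)
        vc = reml_fit((F, M), y)
        ll = restricted_log_likelihood((F, M), y, vc)
        for df, dm in [(1.3, 1.0), (0.7, 1.0), (1.0, 1.3), (1.0, 0.7)]:
            if vc.sigma2_f == 0 and df != 1.0:
                continue
            if vc.sigma2_m == 0 and dm != 1.0:
                continue
            nudged = VarianceComponents(vc.sigma2_f * df, vc.sigma2_m * dm, vc.sigma2_e)
            assert restricted_log_likelihood((F, M), y, nudged) <= ll + 1e-7


class TestSolveMme:
    def test_agrees_with_dense_oracle_and_gls_route(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 20))
            p_f = int(rng.integers(1, 10))
            p_m = int(rng.integers(1, 10))
            F, M, y = random_instance(rng, n, p_f, p_m)
            vc = VarianceComponents(*rng.uniform(0.3, 2.0, size=3))
            b0_o, u_o, v_o = dense_mme_solution(F, M, y, vc)
            for method in ("mme", "gls"):
                fit = solve_mme((F, M), y, vc, method=method)
                np.testing.assert_allclose(fit.beta0, b0_o, rtol=1e-8, atol=1e-10)
                np.testing.assert_allclose(fit.u_hat, u_o, rtol=1e-8, atol=1e-10)
                np.testing.assert_allclose(fit.v_hat, v_o, rtol=1e-8, atol=1e-10)

    def test_infinite_shrinkage_limit(self, rng):
        F, M, y = random_instance(rng, 10, 4, 4)
        vc = VarianceComponents(1e-14, 1e-14, 1.0)
        fit = solve_mme((F, M), y, vc)
        assert np.abs(fit.u_hat).max() < 1e-10
        assert np.abs(fit.v_hat).max() < 1e-10
        assert fit.beta0 == pytest.approx(y.mean(), rel=1e-6)

    def test_zero_component_drops_block(self, rng):
        F, M, y = random_instance(rng, 12, 3, 3)
        fit = solve_mme((F, M), y, VarianceComponents(0.0, 1.0, 1.0))
        assert np.all(fit.u_hat == 0.0)
        assert np.abs(fit.v_hat).max() > 0

    def test_duplicated_block_ridge_equivalence(self, rng):
        """Duplicating every column of F at half the block variance
        leaves predictions unchanged; each column pair shares its effect
        equally (ridge splits the coefficient across exact duplicates)."""
        n = 8
        F = rng.normal(size=(n, 3))
        M = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        vc = VarianceComponents(0.8, 0.6, 1.0)
        base = solve_mme((F, M), y, vc)
        F_dup = np.hstack([F, F])
        vc_half = VarianceComponents(0.4, 0.6, 1.0)
        dup = solve_mme((F_dup, M), y, vc_half)
        np.testing.assert_allclose(dup.u_hat[:3], dup.u_hat[3:], rtol=1e-9)
        np.testing.assert_allclose(dup.u_hat[:3] + dup.u_hat[3:], base.u_hat, rtol=1e-8)
        yhat_base = base.beta0 + F @ base.u_hat + M @ base.v_hat
        yhat_dup = dup.beta0 + F_dup @ dup.u_hat + M @ dup.v_hat
        np.testing.assert_allclose(yhat_dup, yhat_base, rtol=1e-8)

    def test_near_interpolation_when_shrinkage_vanishes(self, rng):
        """With p >= n and lambda -> 0 the fit interpolates the data."""
        n = 6
        F = rng.normal(size=(n, 8))
        M = rng.normal(size=(n, 8))
        y = rng.normal(size=n)
        fit = solve_mme((F, M), y, VarianceComponents(1.0, 1.0, 1e-10), method="gls")
        yhat = fit.beta0 + F @ fit.u_hat + M @ fit.v_hat
        np.testing.assert_allclose(yhat, y, atol=1e-5)

    def test_scale_equivariance(self, rng):
        F, M, y = random_instance(rng, 12, 4, 3)
        vc = VarianceComponents(0.9, 0.7, 1.2)
        c = 3.0
        vc_c = VarianceComponents(0.9 * c**2, 0.7 * c**2, 1.2 * c**2)
        a = solve_mme((F, M), y, vc)
        b = solve_mme((F, M), c * y, vc_c)
        np.testing.assert_allclose(b.beta0, c * a.beta0, rtol=1e-9)
        np.testing.assert_allclose(b.u_hat, c * a.u_hat, rtol=1e-9)
        np.testing.assert_allclose(b.v_hat, c * a.v_hat, rtol=1e-9)

    def test_row_and_column_permutation_invariance(self, rng):
        F, M, y = random_instance(rng, 10, 5, 5)
        vc = VarianceComponents(0.8, 0.8, 1.0)
        base = solve_mme((F, M), y, vc)
        rows = rng.permutation(10)
        permuted = solve_mme((F[rows], M[rows]), y[rows], vc)
        np.testing.assert_allclose(permuted.u_hat, base.u_hat, rtol=1e-8)
        cols = rng.permutation(5)
        colperm = solve_mme((F[:, cols], M[:, cols]), y, vc)
        np.testing.assert_allclose(colperm.u_hat, base.u_hat[cols], rtol=1e-8)
        yhat_base = base.beta0 + F @ base.u_hat + M @ base.v_hat
        yhat_perm = colperm.beta0 + F[:, cols] @ colperm.u_hat + M[:, cols] @ colperm.v_hat
        np.testing.assert_allclose(yhat_perm, yhat_base, rtol=1e-8)

    def test_shrinkage_monotonicity_in_lambda_f(self, rng):
        F, M, y = random_instance(rng, 15, 6, 4)
        norms = []
        for s2f in [2.0, 1.0, 0.5, 0.1, 0.01]:  # lambda_f increasing
            fit = solve_mme((F, M), y, VarianceComponents(s2f, 0.8, 1.0))
            norms.append(np.sum(fit.u_hat**2))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestPrediction:
    def test_hybrid_prediction_decomposes_into_gcas(self, tiny_dataset):
        from hybridblup.predictors import filter_markers, impute_missing

        ds = tiny_dataset
        markers = impute_missing(filter_markers(ds.markers).matrix, ds.pools)
        design = build_design(ds.hybrids, ds.pools, markers=markers)
        y = ds.hybrids["value"].to_numpy()
        vc = reml_fit(design, y)
        fit = solve_mme(design, y, vc)
        pairs = [("F02", "D03"), ("F05", "D11")]
        yhat = predict_hybrids(fit, pairs, ds.pools, markers=markers)
        g_f = predict_gca(fit, ["F02", "F05"], ds.pools, "female", markers=markers)
        g_m = predict_gca(fit, ["D03", "D11"], ds.pools, "male", markers=markers)
        np.testing.assert_allclose(yhat, fit.beta0 + g_f + g_m, rtol=1e-10)

    def test_all_zero_predictors_give_intercept_and_zero_gca(self, tiny_dataset):
        import pandas as pd

        ds = tiny_dataset
        zeros = pd.DataFrame(
            np.zeros((len(ds.markers), 4)),
            index=ds.markers.index,
            columns=list("abcd"),
        )
        design = build_design(ds.hybrids, ds.pools, markers=zeros)
        y = ds.hybrids["value"].to_numpy()
        fit = solve_mme(design, y, VarianceComponents(1.0, 1.0, 1.0))
        yhat = predict_hybrids(fit, [("F01", "D01")], ds.pools, markers=zeros)
        assert yhat[0] == pytest.approx(fit.beta0)
        g = predict_gca(fit, ["F01"], ds.pools, "female", markers=zeros)
        assert g[0] == 0.0

    def test_gca_recovery_on_noise_free_additive_data(self):
        """With no SCA and no error the predicted GCAs track the true
        line values almost perfectly."""
        from hybridblup import SimulationConfig, simulate_factorial
        from hybridblup.predictors import filter_markers, impute_missing

        ds = simulate_factorial(SimulationConfig(
            n_female_lines=10, n_male_lines=10, n_markers=40, n_transcripts=5,
            n_causal=15, var_sca=0.0, var_error=0.0, missing_marker_rate=0.0,
            seed=21,
        ))
        markers = impute_missing(filter_markers(ds.markers).matrix, ds.pools)
        design = build_design(ds.hybrids, ds.pools, markers=markers)
        y = ds.hybrids["value"].to_numpy()
        vc = reml_fit(design, y)
        fit = solve_mme(design, y, vc)
        g_f = predict_gca(fit, list(ds.pools.female_lines), ds.pools, "female", markers=markers)
        r = np.corrcoef(g_f, ds.truth.gca_f.to_numpy())[0, 1]
        assert r > 0.99

    def test_pool_mismatch_rejected(self, tiny_dataset):
        from hybridblup import ConfigError
        from hybridblup.predictors import filter_markers, impute_missing

        ds = tiny_dataset
        markers = impute_missing(filter_markers(ds.markers).matrix, ds.pools)
        design = build_design(ds.hybrids, ds.pools, markers=markers)
        fit = solve_mme(design, ds.hybrids["value"].to_numpy(),
                        VarianceComponents(1.0, 1.0, 1.0))
        with pytest.raises(ConfigError):
            predict_gca(fit, ["D01"], ds.pools, "female", markers=markers)

    def test_predict_from_design_row_alignment(self, tiny_dataset):
        from hybridblup.predictors import filter_markers, impute_missing

        ds = tiny_dataset
        markers = impute_missing(filter_markers(ds.markers).matrix, ds.pools)
        design = build_design(ds.hybrids, ds.pools, markers=markers)
        fit = solve_mme(design, ds.hybrids["value"].to_numpy(),
                        VarianceComponents(0.5, 0.5, 1.0))
        yhat = predict_from_design(fit, design)
        pair = [(ds.hybrids["female"].iloc[7], ds.hybrids["male"].iloc[7])]
        single = predict_hybrids(fit, pair, ds.pools, markers=markers)
        assert single[0] == pytest.approx(yhat[7])
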