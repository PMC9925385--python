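"""Per-variant WLS meta-regression, projection and covariance assembly."""

import numpy as np
import pytest

from tesla_twas.meta_regression import (
    ancestry_projection,
    effect_covariance,
    fit_variant_meta_regression,
    project_effects,
)
from tesla_twas.simulator import ar1_correlation


def _design(u):
    u = np.asarray(u, dtype=float)
    return np.column_stack([np.ones(len(u)), u])


class TestVariantFit:
    @pytest.mark.parametrize(
        "b, s, expected",
        [
            ((1.0, 3.0), (1.0, 1.0), 2.0),  # equal weights
            ((1.0, 3.0), (1.0, np.sqrt(1 / 3)), 2.5),  # hand-computed (1*1 + 3*3)/(1+3)
        ],
    )
    def test_intercept_only_is_inverse_variance_mean(self, b, s, expected):
        gamma, hat = fit_variant_meta_regression(b, s, np.ones((2, 1)))
        assert gamma[0] == pytest.approx(expected, rel=1e-12)
        assert hat @ np.asarray(b) == pytest.approx(expected, rel=1e-12)

    def test_noiseless_linear_data_recovered_exactly(self, rng):
        u = rng.normal(size=5)
        g0, g1 = 0.3, -0.8
        b = g0 + g1 * u
        gamma, _ = fit_variant_meta_regression(b, np.full(5, 0.1), _design(u))
        np.testing.assert_allclose(gamma, [g0, g1], rtol=1e-10)

    def test_projection_matches_dense_matrix_oracle(self, rng):
        # random 3-cohort, L=1 fixture vs. explicit (X'WX)^-1 X'W b product
        b = rng.normal(size=3)
        s = rng.uniform(0.5, 2.0, size=3)
        X = _design(rng.normal(size=3))
        xt = np.array([1.0, 0.7])
        gamma, hat = fit_variant_meta_regression(b, s, X, xt)
        W = np.diag(1.0 / s**2)
        oracle = xt @ np.linalg.inv(X.T @ W @ X) @ X.T @ W @ b
        assert hat @ b == pytest.approx(oracle, rel=1e-10)
        assert xt @ gamma == pytest.approx(oracle, rel=1e-10)
        assert project_effects(gamma[:, None], xt)[0] == pytest.approx(oracle, rel=1e-10)


class TestAncestryProjection:
    def _fixture(self, rng, J=4, K=6, L=2, missing=None):
        u = rng.normal(size=(K, 3))
        design = np.column_stack([np.ones(K), u])
        x_tilde = np.r_[1.0, rng.normal(size=3)]
        B = rng.normal(size=(J, K))
        S = rng.uniform(0.05, 0.3, size=(J, K))
        if missing:
            for j, k in missing:
                B[j, k] = np.nan
                S[j, k] = np.nan
        ld = [ar1_correlation(0.5, J)] * K
        proj = ancestry_projection("g", B, S, design, x_tilde, L, ld)
        return proj, B, S, design, x_tilde, ld

    def test_hat_map_identity(self, rng):
        """b_hat equals the hat map applied to the cohort effects, exactly."""
        proj, B, *_ = self._fixture(rng, missing=[(0, 1), (2, 4)])
        np.testing.assert_allclose(
            proj.b_hat, np.nansum(proj.hat_map * np.nan_to_num(B), axis=1), rtol=1e-12
        )

    def test_fe_hat_rows_are_convex_weights(self, rng):
        proj, *_ = self._fixture(rng, L=0)
        assert np.all(proj.hat_map >= 0)
        np.testing.assert_allclose(proj.hat_map.sum(axis=1), 1.0, rtol=1e-12)

    def test_s_hat_is_sqrt_diagonal(self, rng):
        proj, *_ = self._fixture(rng)
        np.testing.assert_allclose(proj.s_hat, np.sqrt(np.diag(proj.sigma_b)), rtol=1e-12)

    def test_sigma_b_is_psd(self, rng):
        for _ in range(5):
            proj, *_ = self._fixture(rng, J=6, K=8)
            assert np.linalg.eigvalsh(proj.sigma_b).min() >= -1e-10

    def test_missing_cohort_excluded_not_imputed(self, rng):
        """A cohort lacking the variant gets hat weight 0; the rest re-normalize."""
        proj, B, S, *_ = self._fixture(rng, L=0, missing=[(1, 3)])
        assert proj.hat_map[1, 3] == 0.0
        ok = np.isfinite(B[1])
        w = 1.0 / S[1, ok] ** 2
        assert proj.b_hat[1] == pytest.approx(w @ B[1, ok] / w.sum(), rel=1e-12)

    def test_downgrade_when_few_cohorts(self, rng):
        # variant present in only 2 cohorts cannot support L=2: flagged, refit at L=0
        missing = [(0, k) for k in range(2, 6)]
        proj, B, S, *_ = self._fixture(rng, L=2, missing=missing)
        assert proj.downgrades[0] == 0
        w = 1.0 / S[0, :2] ** 2
        assert proj.b_hat[0] == pytest.approx(w @ B[0, :2] / w.sum(), rel=1e-10)

    def test_identical_coordinates_collapse_to_fe(self, rng):
        """With all cohorts at the same PC position, L>=1 reduces to the FE estimate."""
        K, J = 6, 3
        design = np.column_stack([np.ones(K), np.full(K, 0.7), np.full(K, -0.2)])
        x_tilde = np.array([1.0, 0.7, -0.2])
        B = rng.normal(size=(J, K))
        S = rng.uniform(0.1, 0.5, size=(J, K))
        ld = [np.eye(J)] * K
        p2 = ancestry_projection("g", B, S, design, x_tilde, 2, ld)
        p0 = ancestry_projection("g", B, S, design, x_tilde, 0, ld)
        assert set(p2.downgrades.values()) == {0}
        np.testing.assert_allclose(p2.b_hat, p0.b_hat, rtol=1e-10)
        np.testing.assert_allclose(p2.s_hat, p0.s_hat, rtol=1e-10)


class TestEffectCovariance:
    def test_single_cohort_identity_ld_gives_diag_s2(self, rng):
        J = 3
        S = rng.uniform(0.1, 0.4, size=(J, 1))
        B = rng.normal(size=(J, 1))
        design = np.ones((1, 1))
        proj = ancestry_projection("g", B, S, design, np.array([1.0]), 0, [np.eye(J)])
        np.testing.assert_allclose(proj.sigma_b, np.diag(S[:, 0] ** 2), rtol=1e-12)

    def test_perfect_ld_gives_unit_correlation(self, rng):
        J, K = 2, 4
        S = np.full((J, K), 0.2)
        B = rng.normal(size=(J, K))
        ld = [np.ones((J, J))] * K
        proj = ancestry_projection("g", B, S, np.ones((K, 1)), np.array([1.0]), 0, ld)
        corr = proj.sigma_b[0, 1] / (proj.s_hat[0] * proj.s_hat[1])
        assert corr == pytest.approx(1.0, rel=1e-12)

    def test_covariance_matches_monte_carlo(self, rng):
        """Assembled Sigma_b agrees with the empirical covariance of simulated b_hat."""
        J, K, L = 4, 3, 1
        n_draws = 20_000
        anc = [0, 0, 1]
        ld = [ar1_correlation(0.7, J), ar1_correlation(0.7, J), ar1_correlation(0.2, J)]
        chols = [np.linalg.cholesky(m) for m in ld]
        S = rng.uniform(0.05, 0.2, size=(J, K))
        design = _design([0.0, 0.1, 1.0])
        x_tilde = np.array([1.0, 0.5])
        B0 = rng.normal(size=(J, K))
        proj = ancestry_projection("g", B0, S, design, x_tilde, L, [ld[a] for a in anc])
        noise = rng.standard_normal((n_draws, J, K))
        for k in range(K):
            noise[:, :, k] = noise[:, :, k] @ chols[anc[k]].T * S[:, k]
        bhat_draws = (proj.hat_map[None, :, :] * noise).sum(axis=2)
        emp = np.cov(bhat_draws, rowvar=False)
        sig = proj.sigma_b
        mc_se = np.sqrt(
            (np.outer(np.diag(sig), np.diag(sig)) + sig**2) / n_draws
        )
        assert np.all(np.abs(emp - sig) < 3 * mc_se + 1e-12)


class TestParameterRecovery:
    def test_gamma_unbiased_over_replicates(self, rng):
        """Data simulated under M^[1] with known gamma: mean gamma_hat within 3 se."""
        K, reps = 8, 1000
        u = rng.normal(size=K)
        X = _design(u)
        s = rng.uniform(0.1, 0.3, size=K)
        gamma_true = np.array([0.05, -0.12])
        estimates = np.empty((reps, 2))
        for r in range(reps):
            b = X @ gamma_true + rng.normal(scale=s)
            estimates[r], _ = fit_variant_meta_regression(b, s, X)
        se_mean = estimates.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(estimates.mean(axis=0) - gamma_true) < 3 * se_mean)


def test_effect_covariance_requires_ld_per_cohort(rng):
    with pytest.raises(ValueError, match="per cohort"):
        effect_covariance(np.ones((2, 3)), np.ones((2, 3)), np.ones((2, 3)), [np.eye(2)])
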