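"""Gene-level statistics, minimal-P combination, Cauchy combination, comparators."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri
from scipy.stats import kstest

from tesla_twas import tesla_core as tc
from tesla_twas.meta_regression import ancestry_projection
from tesla_twas.simulator import ar1_correlation


class TestTwasStatistic:
    def test_single_variant_reduces_to_marginal_test(self):
        st = tc.twas_statistic(np.array([2.5]), np.array([0.04]), np.array([0.02]),
                               np.array([[0.0004]]))
        assert abs(st.T) == pytest.approx(2.0, rel=1e-12)
        assert st.p == pytest.approx(2 * ndtr(-2.0), rel=1e-12)

    def test_degenerate_cancellation_flagged_untestable(self):
        # w = (1, -1) on two perfectly correlated variants with equal scale: V = 0
        s = np.array([0.1, 0.1])
        sigma = np.outer(s, s)  # correlation exactly 1
        st = tc.twas_statistic(np.array([1.0, -1.0]), np.array([0.2, 0.2]), s, sigma)
        assert not st.testable

    def test_all_zero_weights_untestable(self):
        st = tc.twas_statistic(np.zeros(3), np.ones(3), np.ones(3), np.eye(3))
        assert not st.testable

    def test_matches_dense_quadratic_form_oracle(self, rng):
        J = 4
        w = rng.normal(size=J)
        b = rng.normal(size=J)
        a_ = rng.normal(size=(J, J))
        sigma = a_ @ a_.T
        s = np.sqrt(np.diag(sigma))
        st = tc.twas_statistic(w, b, s, sigma)
        d_inv = np.diag(1.0 / s)
        u_oracle = w @ d_inv @ b
        v_oracle = w @ d_inv @ sigma @ d_inv @ w
        assert st.U == pytest.approx(u_oracle, rel=1e-10)
        assert st.V == pytest.approx(v_oracle, rel=1e-10)
        assert st.T == pytest.approx(u_oracle / np.sqrt(v_oracle), rel=1e-10)

    def test_missing_projected_effects_drop_out(self, rng):
        w = np.array([1.0, 2.0, 3.0])
        b = np.array([0.1, np.nan, 0.3])
        s = np.array([0.2, np.nan, 0.4])
        sigma = np.diag([0.04, np.nan, 0.16])
        sigma[np.isnan(sigma)] = 0.0
        st = tc.twas_statistic(w, b, s, sigma)
        st2 = tc.twas_statistic(w[[0, 2]], b[[0, 2]], s[[0, 2]], np.diag([0.04, 0.16]))
        assert st.T == pytest.approx(st2.T, rel=1e-12)


class TestModelCorrelation:
    def test_single_cohort_all_models_identical(self, rng):
        """With one cohort the PCs carry no information: R_T is all ones."""
        J = 3
        B = rng.normal(size=(J, 1))
        S = np.full((J, 1), 0.1)
        design = np.array([[1.0, 0.3]])
        x_tilde = np.array([1.0, 0.3])
        ld = [ar1_correlation(0.4, J)]
        res = tc.analyze_gene("g", "t", rng.normal(size=J), B, S, design, x_tilde, ld,
                              orders=(0, 1), comparators=())
        np.testing.assert_allclose(res.R_T, 1.0, atol=1e-8)
        assert res.stats[0].p == pytest.approx(res.stats[1].p, rel=1e-10)


class TestMinP:
    def test_perfect_correlation_returns_p_min(self):
        R = np.ones((4, 4))
        assert tc.minp_pvalue([0.2, 0.05, 0.4, 0.6], R) == pytest.approx(0.05, rel=1e-12)

    def test_independence_closed_form(self):
        p = 0.02
        got = tc.minp_pvalue([p, p, p, p], np.eye(4))
        assert got == pytest.approx(1 - (1 - p) ** 4, rel=1e-6)

    def test_single_model_is_identity(self):
        assert tc.minp_pvalue([0.123], np.eye(1)) == pytest.approx(0.123)

    def test_bounded_between_pmin_and_bonferroni(self, rng):
        R = tc.nearest_correlation(np.full((4, 4), 0.3) + 0.7 * np.eye(4))
        for pmin in (0.04, 0.008, 3e-4):
            p_star = tc.minp_pvalue([pmin, 0.5, 0.5, 0.5], R)
            assert pmin <= p_star <= 4 * pmin

    def test_monotone_in_p_min(self):
        R = np.full((4, 4), 0.5) + 0.5 * np.eye(4)
        grid = [1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.2]
        vals = [tc.minp_pvalue([p, 0.9, 0.9, 0.9], R) for p in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo_rectangle(self, rng):
        """Genz quasi-MC rectangle agrees with a plain 10^6-draw Monte Carlo."""
        R = np.full((4, 4), 0.5) + 0.5 * np.eye(4)
        chol = np.linalg.cholesky(R)
        draws = rng.standard_normal((1_000_000, 4)) @ chol.T
        p_min = 0.01
        t = -ndtri(p_min / 2)
        inside = np.all(np.abs(draws) < t, axis=1).mean()
        mc = 1 - inside
        mc_se = np.sqrt(inside * (1 - inside) / 1_000_000)
        assert abs(tc.minp_pvalue([p_min, 0.5, 0.5, 0.5], R) - mc) < 3 * mc_se

    def test_deterministic(self):
        R = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        a = tc.minp_pvalue([0.01, 0.3, 0.7], R)
        b = tc.minp_pvalue([0.01, 0.3, 0.7], R)
        assert a == b


class TestCauchyCombination:
    def test_single_p_is_identity(self):
        assert tc.cauchy_combine([0.37]) == pytest.approx(0.37, rel=1e-12)

    def test_symmetric_pair_gives_half(self):
        assert tc.cauchy_combine([0.25, 0.75]) == pytest.approx(0.5, rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tc.cauchy_combine([0.5, 1.0])
        with pytest.raises(ValueError):
            tc.cauchy_combine([0.0, 0.5])

    def test_tissue_order_invariant(self, rng):
        p = rng.uniform(0.01, 0.99, size=10)
        assert tc.cauchy_combine(p) == pytest.approx(tc.cauchy_combine(p[::-1]), rel=1e-12)

    def test_small_p_asymptotic_is_continuous(self):
        lo = tc.cauchy_combine([9.9e-16, 0.5])
        hi = tc.cauchy_combine([1.01e-15, 0.5])
        assert lo == pytest.approx(hi, rel=1e-2)
        assert 0 < lo < 1e-14

    def test_null_calibration_48_tissues(self, rng):
        """10,000 null replicates of 48 uniform p-values: size ~ alpha at 0.05."""
        reps = 10_000
        p = rng.uniform(size=(reps, 48))
        terms = np.tan((0.5 - p) * np.pi).mean(axis=1)
        combined = 0.5 - np.arctan(terms) / np.pi
        rate = (combined < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.005

    def test_combine_tissues_weights_default_equal(self):
        res = tc.combine_tissues("g", {"a": 0.25, "b": 0.75})
        assert res.p_combined == pytest.approx(0.5, rel=1e-12)
        assert res.weights == {"a": 0.5, "b": 0.5}


class TestComparators:
    def _fixture(self, rng, J=4, K=5):
        B = rng.normal(scale=0.05, size=(J, K))
        S = rng.uniform(0.02, 0.08, size=(J, K))
        ld = [ar1_correlation(0.5, J)] * K
        w = rng.normal(size=J)
        return w, B, S, ld

    def test_fe_equals_model_order_zero(self, rng):
        w, B, S, ld = self._fixture(rng)
        design = np.column_stack([np.ones(5), rng.normal(size=(5, 2))])
        x_tilde = np.r_[1.0, rng.normal(size=2)]
        res = tc.analyze_gene("g", "t", w, B, S, design, x_tilde, ld,
                              orders=(0, 1, 2), comparators=("fe",))
        assert res.p_fe == pytest.approx(res.stats[0].p, rel=1e-12)

    def test_single_study_collapse(self, rng):
        """One cohort: FE, RE and the matching ancestry subset coincide."""
        w, B, S, ld = self._fixture(rng, K=1)
        fe = tc.fe_twas(w, B, S, ld)
        re = tc.re_twas(w, B, S, ld)
        sub = tc.subset_twas(w, B, S, ld, ["EUR"], "EUR")
        assert fe.p == pytest.approx(re.p, rel=1e-12) == pytest.approx(sub.p, rel=1e-12)

    def test_zero_heterogeneity_re_collapses_to_fe(self, rng):
        # identical effects in every cohort -> Q = 0 -> tau2 = 0 -> RE == FE
        J, K = 3, 6
        b_row = rng.normal(size=J)
        B = np.tile(b_row[:, None], (1, K))
        S = np.full((J, K), 0.1)
        ld = [np.eye(J)] * K
        w = rng.normal(size=J)
        _, _, tau2, _ = tc.dersimonian_laird(B[0], S[0])
        assert tau2 == 0.0
        assert tc.re_twas(w, B, S, ld).p == pytest.approx(tc.fe_twas(w, B, S, ld).p, rel=1e-12)

    def test_subset_requires_matching_ancestry(self, rng):
        w, B, S, ld = self._fixture(rng)
        with pytest.raises(ValueError, match="ancestry"):
            tc.subset_twas(w, B, S, ld, ["AFR"] * 5, "EUR")


class TestDiagnostics:
    def test_gc_lambda_near_one_for_uniform(self, rng):
        p = rng.uniform(size=20_000)
        assert tc.genomic_control_lambda(p) == pytest.approx(1.0, abs=0.03)

    def test_untestable_pvalues_are_nan_not_dropped(self, rng):
        res = tc.analyze_gene(
            "g", "t", np.zeros(2), np.full((2, 2), np.nan), np.full((2, 2), np.nan),
            np.ones((2, 1)), np.array([1.0]), [np.eye(2)] * 2, orders=(0,), comparators=(),
        )
        assert np.isnan(res.p_star)
        assert res.n_variants_used == 0


def test_null_pvalues_uniform_end_to_end(default_data, rng):
    """T statistics under the global null produce uniform minimal-P p-values."""
    from tesla_twas.simulator import simulate_effect_matrix, true_effects

    data = default_data
    ps = []
    for _ in range(400):
        w = rng.normal(size=10)
        B = simulate_effect_matrix(data, true_effects(data, w), rng)
        res = tc.analyze_gene("g", "t", w, B, data.S, data.design, data.x_tilde,
                              data.ld_by_cohort, comparators=())
        ps.append(res.p_star)
    assert kstest(ps, "uniform").pvalue > 0.01
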