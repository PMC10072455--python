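"""Noncentral chi-square machinery and asymptotic bias/risk evaluators."""

import numpy as np
import pytest
from scipy import stats

from carliu.asymptotics import (
    LocalAlternative,
    asymptotic_bias,
    asymptotic_quadratic_bias,
    aq_printed_expansion,
    asymptotic_risk,
    build_context,
    inv_moment,
    noncentral_chi2_cdf,
    truncated_inv_moment,
    xi_for_delta,
)
from carliu.errors import DomainError
from carliu.simulation import gen_design, monte_carlo_risk


class TestChiSquareMachinery:
    @pytest.mark.parametrize("df,delta", [(4, 0.0), (4, 2.0), (12, 7.5), (3, 0.3)])
    def test_cdf_series_matches_scipy(self, df, delta):
        for x in (0.5, 3.0, 10.0, 25.0):
            ours = noncentral_chi2_cdf(x, df, delta)
            ref = stats.ncx2.cdf(x, df, delta) if delta > 0 else stats.chi2.cdf(x, df)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_cdf_degenerate_cases(self):
        assert noncentral_chi2_cdf(0.0, 5, 3.0) == 0.0
        assert noncentral_chi2_cdf(4.0, 5, 0.0) == pytest.approx(stats.chi2.cdf(4.0, 5))

    def test_cdf_decreasing_in_delta(self):
        vals = [noncentral_chi2_cdf(8.0, 6, dl) for dl in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_central_inverse_moments_closed_form(self):
        assert inv_moment(10, 1, 0.0) == pytest.approx(1.0 / 8)
        assert inv_moment(10, 2, 0.0) == pytest.approx(1.0 / (8 * 6))

    def test_inverse_moment_against_sampling_oracle(self):
        r = np.random.default_rng(7)
        draws = stats.ncx2.rvs(12, 3.0, size=400_000, random_state=r)
        mc = np.mean(1.0 / draws)
        se = np.std(1.0 / draws) / np.sqrt(draws.size)
        assert abs(inv_moment(12, 1, 3.0) - mc) < 4 * se

    def test_truncated_complementarity(self):
        for df, delta, c in ((12, 3.0, 8.0), (6, 0.0, 2.0), (8, 1.5, 6.0)):
            upper = truncated_inv_moment(df, 1, delta, c, ">")
            lower = truncated_inv_moment(df, 1, delta, c, "<=")
            assert upper + lower == pytest.approx(inv_moment(df, 1, delta), abs=1e-9)

    def test_truncated_zero_cutoff_is_full_moment(self):
        assert truncated_inv_moment(8, 1, 2.0, 0.0, ">") == pytest.approx(
            inv_moment(8, 1, 2.0))

    def test_truncated_matches_sampling_oracle(self):
        r = np.random.default_rng(8)
        draws = stats.ncx2.rvs(12, 3.0, size=400_000, random_state=r)
        vals = (1.0 / draws) * (draws > 8.0)
        mc, se = vals.mean(), vals.std() / np.sqrt(draws.size)
        assert abs(truncated_inv_moment(12, 1, 3.0, 8.0, ">") - mc) < 4 * se

    def test_nonfinite_moment_rejected(self):
        with pytest.raises(DomainError):
            inv_moment(2, 1, 0.0)
        with pytest.raises(DomainError):
            inv_moment(4, 2, 1.0)


@pytest.fixture(scope="module")
def ctx100():
    from carliu.weights import lattice_weights

    w = lattice_weights(10, "queen")
    rng = np.random.default_rng(5)
    X = gen_design(100, 15, 0.3, rng)
    beta = np.concatenate([np.ones(5), np.zeros(10)])
    ctx = build_context(w, X, beta, sigma2=1.0, d=0.5, n_main=5, rho=0.5, alpha=0.05)
    return w, X, ctx


class TestContext:
    def test_block_reconstruction(self, ctx100):
        _, _, ctx = ctx100
        C = np.block([[ctx.C11, ctx.C12], [ctx.C12.T, ctx.C22]])
        np.testing.assert_allclose(C, ctx.C, atol=1e-12)

    def test_d_one_kills_lambda(self, ctx100):
        w, X, _ = ctx100
        beta = np.concatenate([np.ones(5), np.zeros(10)])
        ctx1 = build_context(w, X, beta, 1.0, d=1.0, n_main=5, rho=0.5)
        np.testing.assert_allclose(ctx1.lam, 0.0, atol=1e-12)
        np.testing.assert_allclose(ctx1.a1, 0.0, atol=1e-12)

    def test_xi_zero_shifts_vanish(self, ctx100):
        _, _, ctx = ctx100
        alt = LocalAlternative(np.zeros(10))
        lam112, pi, gamma = ctx.printed_vectors(alt)
        np.testing.assert_allclose(pi, 0.0, atol=1e-12)
        np.testing.assert_allclose(gamma, lam112, atol=1e-12)
        m1, m2, pi3 = ctx.plugin_means(alt)
        np.testing.assert_allclose(m2, ctx.a2, atol=1e-12)
        np.testing.assert_allclose(pi3, m1 - m2, atol=1e-12)

    def test_xi_for_delta_round_trip(self, ctx100):
        _, _, ctx = ctx100
        for target in (0.5, 2.0):
            alt = xi_for_delta(ctx, target)
            assert ctx.noncentrality(alt) == pytest.approx(target)


class TestBiasAndQuadraticBias:
    def test_lus_minus_lu_bias_is_pi_printed(self, ctx100):
        _, _, ctx = ctx100
        alt = xi_for_delta(ctx, 1.5, mode="printed")
        ab_lu = asymptotic_bias("LU", ctx, alt, mode="printed")
        ab_lus = asymptotic_bias("LUS", ctx, alt, mode="printed")
        _, pi, _ = ctx.printed_vectors(alt)
        np.testing.assert_allclose(ab_lus - ab_lu, pi, atol=1e-10)

    def test_pretest_bias_tends_to_full_as_alpha_to_one(self, ctx100):
        w, X, _ = ctx100
        beta = np.concatenate([np.ones(5), np.zeros(10)])
        ctx = build_context(w, X, beta, 1.0, d=0.5, n_main=5, rho=0.5, alpha=1 - 1e-9)
        alt = xi_for_delta(ctx, 2.0)
        np.testing.assert_allclose(
            asymptotic_bias("PTL", ctx, alt),
            asymptotic_bias("LU", ctx, alt), atol=1e-6)

    def test_quadratic_bias_nonnegative_and_zero_at_null(self, ctx100):
        w, X, _ = ctx100
        beta = np.concatenate([np.ones(5), np.zeros(10)])
        ctx1 = build_context(w, X, beta, 1.0, d=1.0, n_main=5, rho=0.5)
        alt0 = LocalAlternative(np.zeros(10))
        # d = 1 and xi = 0: no bias at all for LU/LUS
        assert asymptotic_quadratic_bias("LU", ctx1, alt0) == pytest.approx(0.0, abs=1e-20)
        assert asymptotic_quadratic_bias("LUS", ctx1, alt0) == pytest.approx(0.0, abs=1e-20)
        ctx = ctx100[2]
        alt = xi_for_delta(ctx, 1.0)
        for tag in ("LU", "LUS", "PTL", "SL", "PSL"):
            assert asymptotic_quadratic_bias(tag, ctx, alt) >= 0.0

    def test_printed_expansions_match_definition(self, ctx100):
        # the printed AQ displays for LU/LUS/PTL/SL are exact expansions of
        # AB' B11.2 AB; any mismatch flags a printed-formula defect
        _, _, ctx = ctx100
        alt = xi_for_delta(ctx, 1.2, mode="printed")
        for tag in ("LU", "LUS", "PTL", "SL"):
            a = asymptotic_quadratic_bias(tag, ctx, alt, mode="printed")
            b = aq_printed_expansion(tag, ctx, alt)
            assert a == pytest.approx(b, rel=1e-8, abs=1e-12)


class TestRisk:
    def test_lus_beats_lu_under_null(self, ctx100):
        _, _, ctx = ctx100
        alt0 = LocalAlternative(np.zeros(10))
        assert asymptotic_risk("LUS", ctx, alt0) < asymptotic_risk("LU", ctx, alt0)

    def test_sl_risk_tends_to_lu_for_large_delta(self, ctx100):
        _, _, ctx = ctx100
        alt = xi_for_delta(ctx, 2000.0)
        qr_sl = asymptotic_risk("SL", ctx, alt)
        qr_lu = asymptotic_risk("LU", ctx, alt)
        assert qr_sl == pytest.approx(qr_lu, rel=0.01)

    def test_plugin_risk_matches_monte_carlo(self, ctx100):
        w, X, ctx = ctx100
        beta1 = np.ones(5)
        for target in (0.0, 1.0):
            alt = xi_for_delta(ctx, target)
            mc = monte_carlo_risk(w, X, beta1, alt.xi, rho=0.5, sigma2=1.0,
                                  d=0.5, n_reps=400, seed=3)
            for tag in ("LU", "LUS", "PTL", "SL", "PSL"):
                q = asymptotic_risk(tag, ctx, alt)
                row = mc[mc.estimator == tag].iloc[0]
                assert abs(q - row.risk) / row.risk < 0.12

    def test_printed_mode_evaluates_finite(self, ctx100):
        _, _, ctx = ctx100
        alt = xi_for_delta(ctx, 1.0, mode="printed")
        for tag in ("LU", "LUS", "PTL", "SL", "PSL"):
            assert np.isfinite(asymptotic_risk(tag, ctx, alt, mode="printed"))

    def test_shrinkage_tags_need_p2_above_two(self, ctx100):
        w, X, _ = ctx100
        beta = np.concatenate([np.ones(5), np.zeros(10)])
        ctx2 = build_context(w, X[:, :7], beta[:7], 1.0, d=0.5, n_main=5, rho=0.5)
        with pytest.raises(DomainError):
            asymptotic_risk("SL", ctx2, LocalAlternative(np.zeros(2)))
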