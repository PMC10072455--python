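"""Liu filter, partitioned estimators, pretest and shrinkage combiners."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carliu.errors import DomainError
from carliu.liu import (
    PartitionedCAR,
    PretestResult,
    beta1_full,
    beta1_sub,
    d_optimal,
    liu_filter,
    liu_sub,
    positive_shrinkage_estimator,
    pretest_estimator,
    residual_projection,
    shrinkage_estimator,
)
from carliu.model import CAR


class TestResidualProjection:
    def test_empty_block_returns_precision(self, rng):
        V = np.diag(rng.uniform(1, 2, size=6))
        np.testing.assert_allclose(residual_projection(V, None), V)

    def test_annihilates_projected_block(self, queen7, rng):
        Vinv = queen7.precision(0.4)
        X2 = rng.normal(size=(queen7.n_sites, 4))
        A = residual_projection(Vinv, X2)
        assert np.max(np.abs(A @ X2)) < 1e-10
        assert np.allclose(A, A.T)
        assert np.min(np.linalg.eigvalsh(A)) > -1e-10

    def test_identity_weight_is_ols_residual_maker(self, rng):
        X2 = rng.normal(size=(12, 3))
        A = residual_projection(np.eye(12), X2)
        M = np.eye(12) - X2 @ np.linalg.solve(X2.T @ X2, X2.T)
        np.testing.assert_allclose(A, M, atol=1e-12)


class TestPartitionedEstimates:
    def test_beta1_full_equals_joint_gls_subvector(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=11)
        res = CAR(Y, X, queen7).fit()
        Vinv = queen7.precision(res.rho)
        b1 = beta1_full(Y, X[:, :5], X[:, 5:], Vinv)
        np.testing.assert_allclose(b1, res.params[:5], atol=1e-8)

    def test_identity_through_submodel_estimate(self, queen7, sim_dataset):
        # beta1_hat = beta1_SM - (X1'Vinv X1)^{-1}(X1'Vinv X2) beta2_hat
        Y, X, _ = sim_dataset(seed=12)
        res = CAR(Y, X, queen7).fit()
        Vinv = queen7.precision(res.rho)
        X1, X2 = X[:, :5], X[:, 5:]
        b1 = beta1_full(Y, X1, X2, Vinv)
        bsm = beta1_sub(Y, X1, Vinv)
        corr = np.linalg.solve(X1.T @ Vinv @ X1, X1.T @ Vinv @ X2) @ res.params[5:]
        np.testing.assert_allclose(b1, bsm - corr, atol=1e-8)

    def test_orthogonal_blocks_make_full_equal_sub(self, rook3):
        # X1, X2 orthogonal under the identity-like weight at rho=0 needs
        # D-weighted orthogonality; construct it explicitly
        w = rook3
        Vinv = w.precision(0.0)
        X1 = np.ones((9, 1))
        X2 = np.linalg.qr(np.random.default_rng(0).normal(size=(9, 2)))[0]
        X2 = X2 - X1 @ (X1.T @ Vinv @ X2) / (X1.T @ Vinv @ X1).item()
        Y = np.random.default_rng(1).normal(size=9)
        np.testing.assert_allclose(
            beta1_full(Y, X1, X2, Vinv), beta1_sub(Y, X1, Vinv), atol=1e-10
        )


class TestLiuFilter:
    def test_d_one_is_identity(self, rng):
        A = rng.normal(size=(4, 4))
        M = A @ A.T + np.eye(4)
        b = rng.normal(size=4)
        np.testing.assert_allclose(liu_filter(M, 1.0) @ b, b, atol=1e-12)

    def test_spectral_shrink_factors(self, rng):
        A = rng.normal(size=(5, 5))
        M = A @ A.T + 0.1 * np.eye(5)
        d = 0.3
        mu, U = np.linalg.eigh(M)
        F = liu_filter(M, d)
        # in the eigenbasis the filter is diagonal with (mu + d)/(mu + 1)
        np.testing.assert_allclose(U.T @ F @ U, np.diag((mu + d) / (mu + 1)), atol=1e-10)

    def test_d_zero_identity_M_halves(self):
        b = np.array([2.0, -4.0])
        np.testing.assert_allclose(liu_filter(np.eye(2), 0.0) @ b, b / 2)

    def test_scalar_submodel_case(self):
        m = 3.0
        ds = 0.25
        out = liu_sub(np.array([2.0]), np.sqrt(m) * np.ones((1, 1)), np.eye(1), ds)
        assert out[0] == pytest.approx(2.0 * (m + ds) / (m + 1.0))

    def test_domain_error(self):
        with pytest.raises(DomainError):
            liu_filter(np.eye(2), 1.5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.01, max_value=0.99), st.integers(0, 1000))
    def test_filter_eigencoordinates_bounded(self, d, seed):
        r = np.random.default_rng(seed)
        A = r.normal(size=(4, 4))
        M = A @ A.T + 0.05 * np.eye(4)
        mu = np.linalg.eigvalsh(M)
        f = np.linalg.eigvals(liu_filter(M, d)).real
        lo = (mu.min() + d) / (mu.min() + 1.0)
        assert np.all(f > lo - 1e-10) and np.all(f < 1.0)


class TestDOptimal:
    def test_arithmetic_cases(self):
        assert d_optimal(1, 1.0, np.array([1.0])) == pytest.approx(1e-6)  # clipped at 0
        p, s2 = 4, 2.0
        beta = np.sqrt(3 * p * s2) * np.array([1.0])  # beta'beta = 3 p sigma2
        assert d_optimal(p, s2, beta) == pytest.approx(0.5)
        assert d_optimal(2, 1.0, 1e9 * np.ones(2)) == pytest.approx(1 - 1e-6)

    def test_invalid_sigma2(self):
        with pytest.raises(DomainError):
            d_optimal(2, 0.0, np.ones(2))


class TestCombiners:
    lu = np.array([1.0, 2.0])
    lus = np.array([0.0, 1.0])

    def _pretest(self, Ln, crit=5.0):
        return PretestResult(Ln=Ln, S2=1.0, critical_value=crit,
                             reject=Ln > crit, alpha=0.05, df=4)

    def test_pretest_binary_choice(self):
        np.testing.assert_array_equal(
            pretest_estimator(self.lu, self.lus, self._pretest(10.0)), self.lu)
        np.testing.assert_array_equal(
            pretest_estimator(self.lu, self.lus, self._pretest(2.0)), self.lus)

    def test_alpha_to_one_always_full(self):
        # critical value -> 0: any positive Ln rejects
        np.testing.assert_array_equal(
            pretest_estimator(self.lu, self.lus, self._pretest(1e-9, crit=0.0)), self.lu)

    def test_shrinkage_at_Ln_equal_p2_minus_2(self):
        np.testing.assert_allclose(
            shrinkage_estimator(self.lu, self.lus, 2.0, 4), self.lus)

    def test_shrinkage_limit_large_Ln(self):
        np.testing.assert_allclose(
            shrinkage_estimator(self.lu, self.lus, 1e12, 4), self.lu, rtol=1e-9)

    def test_p2_two_returns_full(self):
        np.testing.assert_allclose(
            shrinkage_estimator(self.lu, self.lus, 7.0, 2), self.lu)

    def test_positive_part_truncates(self):
        Ln = 1.0  # < p2 - 2 = 2: SL overshoots past LUS, PSL stays at LUS
        sl = shrinkage_estimator(self.lu, self.lus, Ln, 4)
        psl = positive_shrinkage_estimator(self.lu, self.lus, Ln, 4)
        np.testing.assert_allclose(psl, self.lus)
        # SL lies beyond LUS on the far side of the segment
        assert np.all((sl - self.lus) * (self.lu - self.lus) < 0)

    def test_positive_part_equals_sl_above_cutoff(self):
        np.testing.assert_allclose(
            positive_shrinkage_estimator(self.lu, self.lus, 9.0, 4),
            shrinkage_estimator(self.lu, self.lus, 9.0, 4))

    def test_p2_one_rejected(self):
        with pytest.raises(DomainError):
            shrinkage_estimator(self.lu, self.lus, 3.0, 1)


class TestPartitionedFit:
    def test_estimate_set_invariants(self, queen7, sim_dataset):
        for seed in (21, 22, 23):
            Y, X, _ = sim_dataset(seed=seed)
            res = PartitionedCAR(Y, X, queen7, n_main=5).fit()
            pt = res.pretest
            assert pt.reject == (pt.Ln > pt.critical_value)
            chosen = res.lu if pt.reject else res.lus
            np.testing.assert_array_equal(res.ptl, chosen)
            if pt.Ln >= res.model.p2 - 2:
                np.testing.assert_allclose(res.psl, res.sl, atol=1e-12)
            else:
                np.testing.assert_allclose(res.psl, res.lus, atol=1e-12)
            assert pt.S2 > 0 and pt.Ln >= 0

    def test_deterministic(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=24)
        r1 = PartitionedCAR(Y, X, queen7, n_main=5).fit()
        r2 = PartitionedCAR(Y, X, queen7, n_main=5).fit()
        for tag in r1.estimates:
            np.testing.assert_array_equal(r1.estimates[tag], r2.estimates[tag])
        assert r1.pretest.Ln == r2.pretest.Ln

    def test_empty_nuisance_collapses_all(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=25)
        res = PartitionedCAR(Y, X[:, :5], queen7, n_main=5).fit()
        for tag in ("LUS", "PTL", "SL", "PSL"):
            np.testing.assert_allclose(res.estimates[tag], res.lu, atol=1e-12)
        assert res.pretest is None

    def test_p2_one_disables_shrinkage(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=26)
        res = PartitionedCAR(Y, X[:, :6], queen7, n_main=5).fit()
        assert res.sl is None and res.psl is None
        assert res.pretest is not None
        assert "shrinkage_disabled_p2_1" in res.flags

    def test_share_rho_option(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=27)
        res = PartitionedCAR(Y, X, queen7, n_main=5).fit(share_rho=True)
        assert res.sub_results.rho == pytest.approx(res.full_results.rho)

    def test_fixed_d_mode_requires_values(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=28)
        model = PartitionedCAR(Y, X, queen7, n_main=5)
        with pytest.raises(DomainError):
            model.fit(d_mode="fixed")
        res = model.fit(d_mode="fixed", d=0.4, ds=0.6)
        assert res.config.d == 0.4 and res.config.ds == 0.6

    def test_summary_and_to_dict(self, queen7, sim_dataset):
        Y, X, _ = sim_dataset(seed=29)
        res = PartitionedCAR(Y, X, queen7, n_main=5).fit()
        payload = res.to_dict()
        assert set(payload["estimates"]) >= {"LU", "LUS", "PTL", "SL", "PSL"}
        assert "L_n" in res.summary() or "Ln" in str(payload["pretest"])
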