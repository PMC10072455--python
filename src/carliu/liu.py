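"""Liu-type full-model, sub-model, pretest and shrinkage estimators.

The large-scale effect vector is partitioned as ``beta = (beta1, beta2)``
with ``beta1`` the ``p1`` main-effect coefficients and ``beta2`` the ``p2``
nuisance coefficients suspected to be zero (``H0: beta2 = 0``).  Writing
``M`` for the relevant information block, the Liu filter

    ``F(M, d) = (M + I)^{-1} (M + d I)``,   ``0 < d < 1``

is applied to the full-model estimate of ``beta1`` (``M = X1' A2 X1`` with
``A2`` the Vn^{-1}-weighted annihilator of ``X2``) and to the sub-model
estimate (``M = X1' Vn^{-1} X1``), giving the LU and LUS estimators.  A
pretest statistic ``L_n`` for ``H0`` then combines the two:

* PTL -- binary choice: LUS if ``L_n <= chi2_{p2, alpha}``, LU otherwise;
* SL  -- Stein-type smooth weight ``1 - (p2 - 2)/L_n``;
* PSL -- positive part of the SL weight, guarding against over-shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .errors import DataError, DomainError, SingularDesignError
from .model import CAR, CARResults
from .weights import SpatialWeights

__all__ = [
    "LiuConfig",
    "PretestResult",
    "PartitionedCAR",
    "LiuResults",
    "residual_projection",
    "beta1_full",
    "beta1_sub",
    "liu_filter",
    "liu_full",
    "liu_sub",
    "d_optimal",
    "pretest_estimator",
    "shrinkage_estimator",
    "positive_shrinkage_estimator",
]

ESTIMATOR_TAGS = ("LU", "LUS", "PTL", "SL", "PSL")

#: L_n below this guard is treated as exactly zero (over-shrink regime).
_LN_GUARD = 1e-12


@dataclass(frozen=True)
class LiuConfig:
    """Biasing parameters and test level for the estimator set."""

    d: float
    ds: float
    alpha: float = 0.05
    d_mode: str = "optimal"

    def __post_init__(self):
        for name, v in (("d", self.d), ("ds", self.ds)):
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha={self.alpha} outside (0, 1)")


@dataclass(frozen=True)
class PretestResult:
    """Outcome of the nuisance-block significance test."""

    Ln: float
    S2: float
    critical_value: float
    reject: bool
    alpha: float
    df: int


# ----------------------------------------------------------------------
# Elementary operations
# ----------------------------------------------------------------------

def residual_projection(V_inv: np.ndarray, X_other: np.ndarray | None) -> np.ndarray:
    """Weighted annihilator ``A = V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}``.

    ``A`` is symmetric positive semidefinite and satisfies ``A @ X_other = 0``;
    with ``X_other`` empty it is just ``V^{-1}``.
    """
    V_inv = np.asarray(V_inv, dtype=float)
    if X_other is None or X_other.size == 0:
        return V_inv
    VX = V_inv @ X_other
    G = X_other.T @ VX
    try:
        c, low = linalg.cho_factor(G)
    except linalg.LinAlgError as exc:
        raise SingularDesignError("collinear nuisance block: X' V^{-1} X singular") from exc
    A = V_inv - VX @ linalg.cho_solve((c, low), VX.T)
    return 0.5 * (A + A.T)


def beta1_full(endog, X1, X2, V_inv) -> np.ndarray:
    """Full-model estimate of ``beta1``: ``(X1' A2 X1)^{-1} X1' A2 Y``.

    Numerically equal to the leading ``p1`` sub-vector of the joint GLS
    estimate on ``[X1 X2]``.
    """
    A2 = residual_projection(V_inv, None if X2 is None else np.asarray(X2, dtype=float))
    M = X1.T @ A2 @ X1
    try:
        c, low = linalg.cho_factor(M)
    except linalg.LinAlgError as exc:
        raise SingularDesignError("X1 rank deficient after projecting out X2") from exc
    return linalg.cho_solve((c, low), X1.T @ (A2 @ np.asarray(endog, dtype=float)))


def beta1_sub(endog, X1, V_inv) -> np.ndarray:
    """Sub-model GLS estimate ``(X1' V^{-1} X1)^{-1} X1' V^{-1} Y``."""
    return beta1_full(endog, X1, None, V_inv)


def liu_filter(M: np.ndarray, d: float) -> np.ndarray:
    """Liu shrinkage filter ``(M + I)^{-1} (M + d I)`` for ``d`` in [0, 1]."""
    if not (0.0 <= d <= 1.0):
        raise DomainError(f"biasing parameter d={d} outside [0, 1]")
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    return linalg.solve(M + np.eye(p), M + d * np.eye(p), assume_a="pos")


def liu_full(beta1: np.ndarray, X1: np.ndarray, A2: np.ndarray, d: float) -> np.ndarray:
    """Full-model Liu estimator: filter with ``M = X1' A2 X1``."""
    return liu_filter(X1.T @ A2 @ X1, d) @ beta1


def liu_sub(beta1_sm: np.ndarray, X1: np.ndarray, V_inv: np.ndarray, ds: float) -> np.ndarray:
    """Sub-model Liu estimator: filter with ``M = X1' V^{-1} X1``."""
    return liu_filter(X1.T @ V_inv @ X1, ds) @ beta1_sm


def d_optimal(p: int, sigma2: float, beta: np.ndarray, clip: float = 1e-6) -> float:
    """Data-driven biasing parameter ``d = 1 - 2 p sigma^2 / (p sigma^2 + beta' beta)``.

    The raw value can fall outside (0, 1); it is clipped into
    ``[clip, 1 - clip]``.
    """
    if sigma2 <= 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    bb = float(np.dot(beta, beta))
    d = 1.0 - 2.0 * p * sigma2 / (p * sigma2 + bb)
    return float(np.clip(d, clip, 1.0 - clip))


def pretest_estimator(lu: np.ndarray, lus: np.ndarray, pretest: PretestResult) -> np.ndarray:
    """Binary combiner: LU if the test rejects ``H0``, LUS otherwise."""
    return np.array(lu if pretest.reject else lus, dtype=float, copy=True)


def shrinkage_estimator(lu, lus, Ln: float, p2: int) -> np.ndarray:
    """Stein-type combiner ``lus + (lu - lus) (1 - (p2 - 2)/L_n)``.

    Requires ``p2 >= 2``; for ``L_n`` below the machine guard the sub-model
    estimate (the positive-part limit) is returned.
    """
    if p2 < 2:
        raise DomainError(f"shrinkage estimator requires p2 >= 2, got p2={p2}")
    lu = np.asarray(lu, float)
    lus = np.asarray(lus, float)
    if Ln < _LN_GUARD:
        return lus.copy()
    return lus + (lu - lus) * (1.0 - (p2 - 2.0) / Ln)


def positive_shrinkage_estimator(lu, lus, Ln: float, p2: int) -> np.ndarray:
    """Positive-part combiner: the SL weight truncated at zero."""
    if p2 < 2:
        raise DomainError(f"positive shrinkage requires p2 >= 2, got p2={p2}")
    lu = np.asarray(lu, float)
    lus = np.asarray(lus, float)
    if Ln < _LN_GUARD:
        return lus.copy()
    return lus + (lu - lus) * max(0.0, 1.0 - (p2 - 2.0) / Ln)


# ----------------------------------------------------------------------
# Partitioned model
# ----------------------------------------------------------------------

class PartitionedCAR:
    """CAR model with the design split into main and nuisance blocks.

    Parameters
    ----------
    endog, exog, weights
        As for :class:`~carliu.model.CAR`.
    n_main : int, optional
        Treat the first ``n_main`` columns of ``exog`` as the main block.
    main : sequence of int, optional
        Explicit 0-based column indices of the main block (overrides
        ``n_main``); all remaining columns form the nuisance block.
    """

    def __init__(self, endog, exog, weights: SpatialWeights, n_main: int | None = None,
                 main=None):
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p = X.shape[1]
        if main is None:
            if n_main is None:
                raise DomainError("specify n_main or main column indices")
            main = list(range(n_main))
        self.main_ix = [int(i) for i in main]
        if len(set(self.main_ix)) != len(self.main_ix) or not all(0 <= i < p for i in self.main_ix):
            raise DomainError(f"invalid main column indices {main}")
        self.nuisance_ix = [i for i in range(p) if i not in set(self.main_ix)]
        self.p1 = len(self.main_ix)
        self.p2 = len(self.nuisance_ix)
        if self.p1 < 1:
            raise DomainError("main block must contain at least one column")
        # reorder internally as [X1 X2]
        self._order = self.main_ix + self.nuisance_ix
        self.exog = X[:, self._order]
        self.X1 = self.exog[:, : self.p1]
        self.X2 = self.exog[:, self.p1 :]
        self.endog = np.asarray(endog, dtype=float)
        self.weights = weights
        self._full = CAR(self.endog, self.exog, weights)

    @classmethod
    def from_dataframe(cls, data, response: str, main, nuisance, weights: SpatialWeights,
                       add_intercept: bool = False) -> "PartitionedCAR":
        """Build from dataframe columns; the intercept joins the main block."""
        Y = data[response].to_numpy(dtype=float)
        X1 = data[list(main)].to_numpy(dtype=float)
        X2 = data[list(nuisance)].to_numpy(dtype=float)
        if add_intercept:
            X1 = np.column_stack([np.ones(len(Y)), X1])
        X = np.column_stack([X1, X2])
        return cls(Y, X, weights, n_main=X1.shape[1])

    # ------------------------------------------------------------------
    def fit(
        self,
        alpha: float = 0.05,
        d_mode: str = "optimal",
        d: float | None = None,
        ds: float | None = None,
        share_rho: bool = False,
        s2_residuals: str = "liu",
    ) -> "LiuResults":
        """Fit full and sub models and compute the five estimators.

        Parameters
        ----------
        alpha : float
            Level of the pretest.
        d_mode : {"optimal", "fixed"}
            With ``"optimal"`` the biasing parameters are computed from the
            fitted models (full fit for ``d``, sub fit for ``ds``); with
            ``"fixed"`` both must be supplied.
        share_rho : bool
            Reuse the full-model ``rho_hat`` for the sub model instead of
            refitting its own profile likelihood.
        s2_residuals : {"liu", "mle"}
            Residuals used in the pretest variance ``S^2`` (the Liu
            full-vector fit by default; MLE residuals for sensitivity).
        """
        if d_mode not in ("optimal", "fixed"):
            raise DomainError(f"d_mode must be 'optimal' or 'fixed', got {d_mode!r}")
        if d_mode == "fixed" and (d is None or ds is None):
            raise DomainError("d_mode='fixed' requires explicit d and ds")

        full = self._full.fit()
        if self.p2 == 0:
            sub = full
        elif share_rho:
            sub = CAR(self.endog, self.X1, self.weights).fit(rho=full.rho)
        else:
            sub = CAR(self.endog, self.X1, self.weights).fit()

        p = self.p1 + self.p2
        n = self.endog.shape[0]
        if d_mode == "optimal":
            d = d_optimal(p, full.sigma2, full.params)
            ds = d_optimal(self.p1, sub.sigma2, sub.params[: self.p1])
        config = LiuConfig(d=float(d), ds=float(ds), alpha=alpha, d_mode=d_mode)
        flags: dict[str, bool] = {}

        info_full = full.information()           # X' Vinv X at full rho_hat
        I11 = info_full[: self.p1, : self.p1]
        beta1_mle = full.params[: self.p1]

        if self.p2 == 0:
            lu = liu_filter(I11, config.d) @ beta1_mle
            return LiuResults(self, full, sub, config, beta1_mle, beta1_mle.copy(),
                              lu, lu.copy(), lu.copy(), lu.copy(), lu.copy(), None, flags)

        I12 = info_full[: self.p1, self.p1 :]
        I22 = info_full[self.p1 :, self.p1 :]
        # Schur complements: X1'A2X1 and X2'A1X2 without forming A1/A2
        Mf = I11 - I12 @ linalg.solve(I22, I12.T, assume_a="pos")
        Mg = I22 - I12.T @ linalg.solve(I11, I12, assume_a="pos")
        beta2_mle = full.params[self.p1 :]

        # pretest statistic: full-vector Liu residuals, Vn^{-1} weighting
        if s2_residuals == "liu":
            beta_lu_all = liu_filter(info_full, config.d) @ full.params
            rss = full.weighted_rss(beta_lu_all)
        elif s2_residuals == "mle":
            rss = full.weighted_rss()
        else:
            raise DomainError(f"s2_residuals must be 'liu' or 'mle', got {s2_residuals!r}")
        if rss <= _LN_GUARD:
            raise DataError("degenerate data: weighted residual sum of squares is zero")
        S2 = rss / (n - p)
        Ln = float(beta2_mle @ Mg @ beta2_mle / S2)
        critical = float(stats.chi2.ppf(1.0 - alpha, df=self.p2))
        pretest = PretestResult(Ln=Ln, S2=float(S2), critical_value=critical,
                                reject=Ln > critical, alpha=alpha, df=self.p2)

        lu = liu_filter(Mf, config.d) @ beta1_mle
        Ms = sub.information()
        lus = liu_filter(Ms, config.ds) @ sub.params
        ptl = pretest_estimator(lu, lus, pretest)

        if self.p2 >= 2:
            if self.p2 == 2:
                flags["p2_equals_2"] = True  # shrink factor is 1: SL = PSL = LU
            if Ln < _LN_GUARD:
                flags["over_shrink_guard"] = True
            sl = shrinkage_estimator(lu, lus, Ln, self.p2)
            psl = positive_shrinkage_estimator(lu, lus, Ln, self.p2)
        else:
            flags["shrinkage_disabled_p2_1"] = True
            sl = psl = None

        return LiuResults(self, full, sub, config, beta1_mle, sub.params.copy(),
                          lu, lus, ptl, sl, psl, pretest, flags)


class LiuResults:
    """Estimate set produced by :meth:`PartitionedCAR.fit`.

    Attributes
    ----------
    beta1_mle, beta1_sm : (p1,) ndarray
        Full-model and sub-model ML estimates of the main block.
    lu, lus, ptl, sl, psl : (p1,) ndarray
        The five Liu-type estimators (``sl``/``psl`` are None when the
        nuisance block has a single column).
    pretest : PretestResult or None
        Test record; None when the nuisance block is empty.
    config : LiuConfig
        Resolved biasing parameters and test level.
    full_results, sub_results : CARResults
        The underlying model fits.
    """

    def __init__(self, model, full_results: CARResults, sub_results: CARResults,
                 config: LiuConfig, beta1_mle, beta1_sm, lu, lus, ptl, sl, psl,
                 pretest: PretestResult | None, flags: dict):
        self.model = model
        self.full_results = full_results
        self.sub_results = sub_results
        self.config = config
        self.beta1_mle = beta1_mle
        self.beta1_sm = beta1_sm
        self.lu = lu
        self.lus = lus
        self.ptl = ptl
        self.sl = sl
        self.psl = psl
        self.pretest = pretest
        self.flags = flags

    @property
    def estimates(self) -> dict[str, np.ndarray]:
        out = {"MLE": self.beta1_mle, "SM": self.beta1_sm, "LU": self.lu,
               "LUS": self.lus, "PTL": self.ptl}
        if self.sl is not None:
            out["SL"] = self.sl
            out["PSL"] = self.psl
        return out

    def to_dict(self) -> dict:
        out = {
            "p1": self.model.p1,
            "p2": self.model.p2,
            "main_columns": self.model.main_ix,
            "nuisance_columns": self.model.nuisance_ix,
            "d": self.config.d,
            "ds": self.config.ds,
            "alpha": self.config.alpha,
            "rho_full": self.full_results.rho,
            "rho_sub": self.sub_results.rho,
            "estimates": {k: np.asarray(v).tolist() for k, v in self.estimates.items()},
            "flags": self.flags,
        }
        if self.pretest is not None:
            out["pretest"] = {
                "Ln": self.pretest.Ln,
                "S2": self.pretest.S2,
                "critical_value": self.pretest.critical_value,
                "reject": bool(self.pretest.reject),
            }
        return out

    def summary(self) -> str:
        lines = [
            "Liu-type Estimators for the Main-Effect Block",
            "=" * 60,
            f"p1 = {self.model.p1}, p2 = {self.model.p2}, "
            f"d = {self.config.d:.4f}, ds = {self.config.ds:.4f}, alpha = {self.config.alpha}",
            f"rho_hat (full) = {self.full_results.rho:.4f}, "
            f"rho_hat (sub) = {self.sub_results.rho:.4f}",
        ]
        if self.pretest is not None:
            dec = "reject H0 (use LU)" if self.pretest.reject else "retain H0 (use LUS)"
            lines.append(
                f"L_n = {self.pretest.Ln:.4f}  vs  chi2({self.pretest.df}) "
                f"critical {self.pretest.critical_value:.4f}  ->  {dec}"
            )
        lines.append("-" * 60)
        tags = list(self.estimates)
        lines.append("coef  " + "".join(f"{t:>10}" for t in tags))
        for i in range(self.model.p1):
            row = f"x{self.model.main_ix[i] + 1:<4d}"
            for t in tags:
                row += f"{self.estimates[t][i]:>10.4f}"
            lines.append(row)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LiuResults p1={self.model.p1} p2={self.model.p2}>"
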