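"""Monte Carlo study of the simulated relative efficiencies (SRE).

The experiment follows the standard design for assessing shrinkage under
multicollinearity on a lattice: per replicate, a fresh Gaussian design with
AR(1) column correlation ``rho_x^{|j-k|}`` is drawn, the response is
generated with CAR-correlated errors, both the full and the sub model are
refit by profile likelihood, and the five Liu-type estimators of the main
block are computed.  Per estimator the mean squared error
``sum_i (beta1_i* - beta1_i)^2`` is averaged over replicates and reported
as ``SRE = MSE(baseline) / MSE(estimator)`` (values above one favor the
estimator).  The true coefficient vector is
``beta = (1_{p1}, Delta, 0_{p2-1})`` so that ``Delta = ||beta - beta0||``
measures the violation of ``H0: beta2 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CarliuError, DomainError
from .liu import PartitionedCAR
from .weights import SpatialWeights, lattice_weights

__all__ = [
    "SimDesign",
    "SimResult",
    "gen_design",
    "build_beta",
    "gen_response",
    "run_sre_experiment",
    "monte_carlo_risk",
]

_SIM_TAGS = ("MLE", "SM", "LU", "LUS", "PTL", "SL", "PSL")


def gen_design(n: int, p: int, rho_x: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian design with AR(1) column covariance ``rho_x^{|j-k|}``."""
    if not abs(rho_x) < 1:
        raise DomainError(f"|rho_x| must be < 1, got {rho_x}")
    idx = np.arange(p)
    cov = rho_x ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, p)) @ L.T


def build_beta(p1: int, p2: int, delta: float) -> np.ndarray:
    """``beta = (1_{p1}, Delta, 0_{p2-1})``; ``||beta - beta0|| = Delta``."""
    if p2 < 1:
        raise DomainError("build_beta requires p2 >= 1")
    if delta < 0:
        raise DomainError("Delta must be nonnegative")
    beta = np.zeros(p1 + p2)
    beta[:p1] = 1.0
    beta[p1] = delta
    return beta


def gen_response(
    X: np.ndarray,
    beta: np.ndarray,
    rho: float,
    sigma2: float,
    weights: SpatialWeights,
    rng: np.random.Generator,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """``Y = X beta + eps`` with ``eps ~ N(0, sigma^2 (I - rho Wstar)^{-1} D)``.

    ``chol`` may carry a precomputed Cholesky factor of the (symmetrized)
    covariance factor ``Vn(rho)`` to avoid refactorizing in loops.
    """
    if chol is None:
        chol = np.linalg.cholesky(weights.covariance(rho))
    eps = np.sqrt(sigma2) * (chol @ rng.standard_normal(weights.n_sites))
    return X @ beta + eps


@dataclass(frozen=True)
class SimDesign:
    """Parameterization of one SRE experiment (defaults: the 7x7 study)."""

    N: int = 7
    scheme: str = "queen"
    p1: int = 5
    p2: int = 10
    rho_x: float = 0.3
    rho: float = 0.5
    sigma2: float = 1.0
    delta_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0)
    alpha: float = 0.05
    n_reps: int = 2000
    seed: int = 0
    d_mode: str = "optimal"
    d: float | None = None
    ds: float | None = None
    baseline: str = "MLE"

    def __post_init__(self):
        if self.N * self.N <= self.p1 + self.p2:
            raise DomainError("lattice too small: need n > p1 + p2")
        if self.baseline not in _SIM_TAGS:
            raise DomainError(f"baseline must be one of {_SIM_TAGS}")


@dataclass
class SimResult:
    """Tidy SRE table plus the configuration that produced it."""

    design: SimDesign
    table: pd.DataFrame
    rejection_rate: pd.Series
    n_failed: int

    def sre(self, estimator: str, delta: float) -> float:
        m = self.table[(self.table.estimator == estimator) & (self.table.delta == delta)]
        return float(m.sre.iloc[0])

    def plot(self, ax=None):
        """SRE-versus-Delta curves, one line per estimator."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for tag, grp in self.table.groupby("estimator"):
            if tag == self.design.baseline:
                continue
            ax.plot(grp.delta, grp.sre, marker="o", label=tag)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(r"$\Delta$")
        ax.set_ylabel("SRE")
        ax.set_title(
            f"n={self.design.N ** 2}, (p1,p2)=({self.design.p1},{self.design.p2}), "
            f"rho={self.design.rho}, rho_x={self.design.rho_x}"
        )
        ax.legend()
        return ax


def _replicate_rng(seed: int, delta_index: int, rep: int) -> np.random.Generator:
    """Deterministic per-replicate stream, independent of execution order."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(delta_index, rep))
    return np.random.default_rng(ss)


def _estimate_set(Y, X, weights, p1, alpha, d_mode, d, ds):
    res = PartitionedCAR(Y, X, weights, n_main=p1).fit(
        alpha=alpha, d_mode=d_mode, d=d, ds=ds
    )
    est = dict(res.estimates)
    return est, res


def run_sre_experiment(design: SimDesign, weights: SpatialWeights | None = None) -> SimResult:
    """Run the full SRE sweep over ``design.delta_grid``.

    Replicates failing to fit (for any estimator) are dropped pairwise and
    counted, preserving the paired comparison across estimators.
    """
    if weights is None:
        weights = lattice_weights(design.N, design.scheme)
    n = weights.n_sites
    p = design.p1 + design.p2
    beta1_true = np.ones(design.p1)
    chol = np.linalg.cholesky(weights.covariance(design.rho))

    rows = []
    rejections = {}
    n_failed = 0
    for di, delta in enumerate(design.delta_grid):
        beta = build_beta(design.p1, design.p2, float(delta))
        sq_err = {tag: [] for tag in _SIM_TAGS}
        rej = []
        for rep in range(design.n_reps):
            rng = _replicate_rng(design.seed, di, rep)
            X = gen_design(n, p, design.rho_x, rng)
            Y = gen_response(X, beta, design.rho, design.sigma2, weights, rng, chol=chol)
            try:
                est, res = _estimate_set(Y, X, weights, design.p1, design.alpha,
                                         design.d_mode, design.d, design.ds)
            except (CarliuError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            for tag in _SIM_TAGS:
                e = est.get(tag)
                if e is not None:
                    sq_err[tag].append(float(np.sum((e - beta1_true) ** 2)))
            rej.append(bool(res.pretest.reject))
        rejections[float(delta)] = float(np.mean(rej)) if rej else np.nan

        base = np.asarray(sq_err[design.baseline])
        k = len(base)
        mse_base = base.mean()
        for tag in _SIM_TAGS:
            errs = np.asarray(sq_err[tag])
            if errs.size == 0:  # e.g. SL/PSL disabled for p2 = 1
                continue
            mse = errs.mean()
            mc_se = errs.std(ddof=1) / np.sqrt(k)
            sre = mse_base / mse
            # delta-method SE of the paired ratio of means
            vb = base.var(ddof=1)
            vt = errs.var(ddof=1)
            cvt = np.cov(base, errs, ddof=1)[0, 1]
            sre_var = (sre ** 2 / k) * (
                vb / mse_base ** 2 + vt / mse ** 2 - 2.0 * cvt / (mse_base * mse)
            )
            rows.append({
                "delta": float(delta),
                "estimator": tag,
                "mse": mse,
                "mc_se": mc_se,
                "sre": sre,
                "sre_se": float(np.sqrt(max(sre_var, 0.0))),
                "n_reps": k,
            })

    table = pd.DataFrame(rows)
    return SimResult(design=design, table=table,
                     rejection_rate=pd.Series(rejections, name="rejection_rate"),
                     n_failed=n_failed)


def monte_carlo_risk(
    weights: SpatialWeights,
    X: np.ndarray,
    beta1: np.ndarray,
    xi: np.ndarray,
    rho: float,
    sigma2: float,
    d: float,
    ds: float | None = None,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
    M: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulated risk ``n E[(beta1* - beta1)' M (beta1* - beta1)]``.

    The design ``X`` is held fixed (it defines the information matrices of
    the risk formulas); the true coefficients are
    ``beta = (beta1, xi / sqrt(n))`` per the local-alternative framework,
    and the biasing parameters are held fixed so the simulation matches
    the quantities the formulas describe.  Returns mean risk and Monte
    Carlo standard error per estimator.
    """
    n = weights.n_sites
    p1 = len(beta1)
    if ds is None:
        ds = d
    if M is None:
        M = np.eye(p1)
    beta = np.concatenate([beta1, np.asarray(xi, float) / np.sqrt(n)])
    chol = np.linalg.cholesky(weights.covariance(rho))
    loss = {tag: [] for tag in ("LU", "LUS", "PTL", "SL", "PSL")}
    n_failed = 0
    for rep in range(n_reps):
        rng = _replicate_rng(seed, 0, rep)
        Y = gen_response(X, beta, rho, sigma2, weights, rng, chol=chol)
        try:
            est, _ = _estimate_set(Y, X, weights, p1, alpha, "fixed", d, ds)
        except (CarliuError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for tag in loss:
            dev = est[tag] - beta1
            loss[tag].append(float(n * dev @ M @ dev))
    rows = []
    for tag, vals in loss.items():
        v = np.asarray(vals)
        rows.append({"estimator": tag, "risk": v.mean(),
                     "mc_se": v.std(ddof=1) / np.sqrt(len(v)),
                     "n_reps": len(v), "n_failed": n_failed})
    return pd.DataFrame(rows)
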