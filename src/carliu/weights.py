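"""Spatial neighborhood structures for areal (lattice) data.

The conditional autoregressive (CAR) covariance is built from a binary,
symmetric contiguity matrix ``W`` with zero diagonal.  Three derived objects
appear throughout the model:

* ``Wstar`` -- the row-standardized proximity matrix with entries
  ``w_ij / w_i+`` where ``w_i+`` is the number of neighbors of site *i*;
* ``D`` -- the diagonal matrix with entries ``1 / w_i+``;
* the open interval of spatial-dependence values ``rho`` for which
  ``(I - rho Wstar)^{-1} D`` is symmetric positive definite.

The precision (inverse covariance) of the CAR error vector has the simple
symmetric form ``D^{-1}(I - rho Wstar) = diag(w_i+) - rho W``, linear in
``rho``; this identity drives all the fast linear algebra in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidWeightsError, IsolatedSiteError

__all__ = [
    "SpatialWeights",
    "NeighborhoodSpec",
    "lattice_weights",
    "row_standardize",
    "read_gal",
    "write_gal",
]

_SCHEMES = ("rook", "queen")


def row_standardize(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-standardize a binary contiguity matrix.

    Returns ``(Wstar, D, row_counts)`` where ``Wstar[i, j] = w_ij / w_i+``,
    ``D`` is the diagonal matrix with ``1 / w_i+`` and ``row_counts`` the
    integer neighbor counts ``w_i+``.

    Raises
    ------
    InvalidWeightsError
        If ``W`` is not square, symmetric, binary with zero diagonal.
    IsolatedSiteError
        If any site has no neighbors.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidWeightsError(f"W must be square, got shape {W.shape}")
    if not np.array_equal(W, W.T):
        raise InvalidWeightsError("contiguity matrix must be symmetric")
    if np.any(np.diag(W) != 0):
        raise InvalidWeightsError("contiguity matrix must have a zero diagonal")
    if not np.all(np.isin(W, (0.0, 1.0))):
        raise InvalidWeightsError("contiguity matrix must be binary (0/1)")
    row_counts = W.sum(axis=1)
    if np.any(row_counts == 0):
        bad = np.flatnonzero(row_counts == 0)
        raise IsolatedSiteError(f"isolated site(s) with no neighbors: {bad.tolist()}")
    Wstar = W / row_counts[:, None]
    D = np.diag(1.0 / row_counts)
    return Wstar, D, row_counts.astype(int)


class SpatialWeights:
    """Validated contiguity structure for a set of ``n_sites`` areal units.

    Parameters
    ----------
    W : (n, n) array_like
        Binary symmetric contiguity matrix with zero diagonal and no
        isolated sites.
    site_labels : sequence of str, optional
        Ordered site identifiers; defaults to ``"1" .. "n"``.
    """

    def __init__(self, W, site_labels: Sequence[str] | None = None):
        Wstar, _, row_counts = row_standardize(W)
        self.W = np.asarray(W, dtype=float)
        self.n_sites = self.W.shape[0]
        self.row_counts = row_counts
        self.Wstar = Wstar
        # D stored as its diagonal; `D` property materializes the matrix.
        self._d = 1.0 / row_counts
        if site_labels is None:
            site_labels = [str(i + 1) for i in range(self.n_sites)]
        if len(site_labels) != self.n_sites:
            raise InvalidWeightsError("site_labels length does not match W")
        self.site_labels = list(site_labels)
        # Eigenvalues of Wstar are real: Wstar = D W is similar to the
        # symmetric matrix D^{1/2} W D^{1/2} = W_ij / sqrt(w_i+ w_j+).
        scale = np.sqrt(np.outer(row_counts, row_counts))
        self._eigs = np.linalg.eigvalsh(self.W / scale)

    # ------------------------------------------------------------------
    @property
    def D(self) -> np.ndarray:
        """Diagonal matrix with entries ``1 / w_i+``."""
        return np.diag(self._d)

    @property
    def rho_interval(self) -> tuple[float, float]:
        """Open interval of admissible spatial-dependence values.

        ``(1/lambda_min, 1/lambda_max)`` for the extreme eigenvalues of the
        standardized proximity matrix; the upper end is 1 for
        row-standardized weights.
        """
        lam_min = self._eigs[0]
        lam_max = self._eigs[-1]
        return (1.0 / lam_min, 1.0 / lam_max)

    def _check_rho(self, rho: float) -> None:
        lo, hi = self.rho_interval
        if not (lo < rho < hi):
            raise DomainError(
                f"rho={rho} outside the admissible open interval ({lo:.6g}, {hi:.6g})"
            )

    # ------------------------------------------------------------------
    def precision(self, rho: float) -> np.ndarray:
        """Inverse of the (sigma^2-free) CAR covariance.

        ``Vn^{-1} = D^{-1}(I - rho Wstar) = diag(w_i+) - rho W`` -- symmetric
        for any binary symmetric ``W`` and positive definite for ``rho``
        strictly inside ``rho_interval``.
        """
        self._check_rho(rho)
        return np.diag(self.row_counts.astype(float)) - rho * self.W

    def covariance(self, rho: float) -> np.ndarray:
        """CAR covariance factor ``Vn = (I - rho Wstar)^{-1} D``.

        The model covariance of the error vector is ``sigma^2 * Vn``.  The
        result is symmetrized to absorb round-off before any factorization.
        """
        P = self.precision(rho)
        V = np.linalg.inv(P)
        return 0.5 * (V + V.T)

    def logdet_covariance(self, rho: float) -> float:
        """``log |Vn|`` via the eigenvalues of the standardized matrix.

        ``log|Vn| = log|D| - log|I - rho Wstar|``; the second term is
        ``sum(log(1 - rho * lambda_i))`` over the (real) eigenvalues of
        ``Wstar``.
        """
        self._check_rho(rho)
        return float(-np.sum(np.log(self.row_counts)) - np.sum(np.log1p(-rho * self._eigs)))

    # ------------------------------------------------------------------
    def neighbors(self, i: int) -> list[int]:
        """0-based neighbor indices of site ``i``."""
        return np.flatnonzero(self.W[i]).tolist()

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet representation ``(i, j, w_ij)`` of nonzero entries."""
        ii, jj = np.nonzero(self.W)
        return pd.DataFrame({"i": ii, "j": jj, "w_ij": self.W[ii, jj]})

    def __eq__(self, other) -> bool:
        return isinstance(other, SpatialWeights) and np.array_equal(self.W, other.W)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.rho_interval
        return (
            f"SpatialWeights(n_sites={self.n_sites}, "
            f"rho_interval=({lo:.4f}, {hi:.4f}))"
        )


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Regular-lattice neighborhood specification.

    ``n_side`` is the side length of the square grid (``n = n_side**2``
    sites, ordered row-major) and ``scheme`` is ``"rook"`` (shared edges)
    or ``"queen"`` (shared edges or corners).  No wraparound: boundary
    sites simply have fewer neighbors.
    """

    n_side: int
    scheme: str = "rook"

    def __post_init__(self):
        if self.n_side < 2:
            raise DomainError(f"lattice side must be >= 2, got {self.n_side}")
        if self.scheme not in _SCHEMES:
            raise DomainError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")

    def build(self) -> SpatialWeights:
        return lattice_weights(self.n_side, self.scheme)


def lattice_weights(n_side: int, scheme: str = "rook") -> SpatialWeights:
    """Contiguity weights for a regular ``n_side x n_side`` lattice.

    Sites are indexed row-major (0-based internally).  Rook neighbors share
    an edge; queen neighbors share an edge or a corner.
    """
    spec = NeighborhoodSpec(n_side, scheme)  # validates
    N = spec.n_side
    n = N * N
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    W = np.zeros((n, n))
    for r in range(N):
        for c in range(N):
            i = r * N + c
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < N and 0 <= cc < N:
                    W[i, rr * N + cc] = 1.0
    return SpatialWeights(W)


# ----------------------------------------------------------------------
# GAL text format: header with the number of sites, then for each site a
# line "<id> <neighbor count>" followed by a line with the neighbor ids.
# Ids are written 1-based (format convention); read back 0-based.
# ----------------------------------------------------------------------

def write_gal(weights: SpatialWeights, path) -> None:
    """Write contiguity lists in GAL format (1-based ids)."""
    lines = [str(weights.n_sites)]
    for i in range(weights.n_sites):
        nbrs = weights.neighbors(i)
        lines.append(f"{i + 1} {len(nbrs)}")
        lines.append(" ".join(str(j + 1) for j in nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path) -> SpatialWeights:
    """Read a GAL contiguity file into validated :class:`SpatialWeights`.

    Symmetry is enforced: a listing ``a -> b`` without ``b -> a`` is an
    error, as are unknown ids and empty neighbor lists.
    """
    tokens = Path(path).read_text().split()
    if not tokens:
        raise InvalidWeightsError("empty GAL file")
    pos = 0
    try:
        n = int(tokens[pos])
    except ValueError as exc:
        raise InvalidWeightsError(f"bad GAL header {tokens[0]!r}") from exc
    pos += 1
    W = np.zeros((n, n))
    seen = set()
    while pos < len(tokens):
        try:
            sid = int(tokens[pos])
            k = int(tokens[pos + 1])
        except (ValueError, IndexError) as exc:
            raise InvalidWeightsError("malformed GAL record") from exc
        pos += 2
        if not (1 <= sid <= n):
            raise InvalidWeightsError(f"unknown site id {sid} (n={n})")
        if k == 0:
            raise IsolatedSiteError(f"site {sid} has an empty neighbor list")
        nbrs = tokens[pos : pos + k]
        if len(nbrs) != k:
            raise InvalidWeightsError(f"site {sid}: expected {k} neighbor ids")
        pos += k
        for tok in nbrs:
            j = int(tok)
            if not (1 <= j <= n):
                raise InvalidWeightsError(f"unknown neighbor id {j} for site {sid}")
            W[sid - 1, j - 1] = 1.0
        seen.add(sid)
    if len(seen) != n:
        raise InvalidWeightsError(f"GAL file lists {len(seen)} of {n} sites")
    if not np.array_equal(W, W.T):
        bad = np.argwhere(W != W.T)
        a, b = bad[0]
        raise InvalidWeightsError(
            f"asymmetric neighbor lists: site {a + 1} lists {b + 1} but not vice versa"
        )
    return SpatialWeights(W)
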