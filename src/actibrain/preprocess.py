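"""Block preprocessing: netmat vectorization, residualization, standardization.

Functional-connectivity network matrices ("netmats", node-by-node partial
correlations) are vectorized to their strict lower triangle with an
element-wise Fisher z-transform, mirroring how imaging pipelines tabulate
edge-level phenotypes.  Confounder effects are removed from each block by
ordinary least-squares residualization before any multivariate analysis
(the "bipartial" design: each block has its own confounder list).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderResidualizer",
    "edge_labels",
    "fisher_z",
    "fisher_z_inverse",
    "residualize_block",
    "standardize",
    "unvectorize_netmat",
    "vectorize_netmat",
]


def fisher_z(r):
    """Fisher z-transform arctanh(r) of a correlation.

    Variance-stabilizing for correlations; strictly increasing and odd.

    Parameters
    ----------
    r : array-like
        Correlation value(s), each with ``|r| < 1``.

    Raises
    ------
    ValueError
        If any ``|r| >= 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def fisher_z_inverse(z):
    """Inverse Fisher transform tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def edge_labels(n_nodes: int) -> list[tuple[int, int]]:
    """Edge index -> (node_i, node_j) for strict lower-triangle, row-major order.

    Edge k corresponds to entry (i, j) with i > j; rows are scanned in
    increasing node order.  This fixed ordering is the vectorization
    convention used throughout the package.
    """
    return [(i, j) for i in range(1, n_nodes) for j in range(i)]


def vectorize_netmat(netmat, *, atol: float = 1e-8):
    """Vectorize a symmetric netmat to Fisher-z edge values.

    The strict lower triangle (row-major node order, diagonal excluded)
    is extracted and each entry mapped by :func:`fisher_z`.  A 55x55
    netmat yields 55*54/2 = 1485 edges.

    Parameters
    ----------
    netmat : (d, d) array-like
        Symmetric within ``atol``; off-diagonal entries in (-1, 1).

    Returns
    -------
    (d*(d-1)/2,) ndarray of Fisher-z edge values.
    """
    M = np.asarray(netmat, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"netmat must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=atol, rtol=0.0):
        raise ValueError(f"netmat asymmetric beyond tolerance {atol}")
    tril = np.tril_indices(M.shape[0], k=-1)
    edges = M[tril]
    if np.any(np.abs(edges) >= 1.0):
        raise ValueError("off-diagonal netmat entries must lie in (-1, 1)")
    return fisher_z(edges)


def unvectorize_netmat(edges, *, diag: float = 1.0):
    """Rebuild a symmetric netmat from Fisher-z edge values.

    Exact inverse of :func:`vectorize_netmat` (unit diagonal by default).
    """
    edges = np.asarray(edges, dtype=float)
    m = edges.shape[0]
    d = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if d * (d - 1) // 2 != m:
        raise ValueError(f"edge vector length {m} is not d*(d-1)/2 for integer d")
    M = np.zeros((d, d))
    tril = np.tril_indices(d, k=-1)
    M[tril] = fisher_z_inverse(edges)
    M = M + M.T
    np.fill_diagonal(M, diag)
    return M


def _add_intercept(G: np.ndarray) -> np.ndarray:
    """Append an intercept column unless one is already in the span."""
    ones = np.ones((G.shape[0], 1))
    if G.size == 0:
        return ones
    # intercept already representable if residual of 1-vector on G is ~0
    coef, *_ = np.linalg.lstsq(G, ones, rcond=None)
    if np.allclose(G @ coef, ones, atol=1e-10):
        return G
    return np.hstack([G, ones])


def residualize_block(Y, G, *, warn_rank_deficient: bool = True):
    """Residualize a data block on a confounder matrix.

    Computes ``Y - G (G'G)^- G' Y`` with a rank-revealing least-squares
    solve; an intercept column is appended to ``G`` if not already in its
    span, so residual columns have exactly zero mean and zero sample
    correlation with every confounder.

    Parameters
    ----------
    Y : (n, q) array-like
    G : (n, p) array-like
        Confounders. May be rank deficient; the projection is then taken
        onto the column space via pseudoinverse (with a logged warning).

    Returns
    -------
    (n, q) ndarray of residuals.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and Y.size > 1:
        Y = Y.T
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != Y.shape[0]:
        raise ValueError("Y and G must have the same number of rows")
    G = _add_intercept(G)
    n, p = G.shape
    if n <= p:
        raise ValueError(f"need n > p confounder columns, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(G)
    if rank < p and warn_rank_deficient:
        logger.warning(
            "confounder matrix is rank deficient (rank %d < %d columns); "
            "projecting via pseudoinverse",
            rank,
            p,
        )
    coef, *_ = np.linalg.lstsq(G, Y, rcond=None)
    return Y - G @ coef


def standardize(X, *, ddof: int = 1):
    """Scale columns to mean 0 and sample standard deviation 1.

    Parameters
    ----------
    X : (n, q) array-like
    ddof : int
        Degrees of freedom for the standard deviation (1 = sample SD).

    Raises
    ------
    ValueError
        Naming the first zero-variance column encountered.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s) at index {zero.tolist()}")
    return (X - mu) / sd


class ConfounderResidualizer(TransformerMixin, BaseEstimator):
    """Transformer removing linear confounder effects from a data block.

    ``fit(X, y=None, confounders=G)`` learns the least-squares projection of
    ``X`` on ``[G, 1]``; ``transform`` subtracts it.  With
    ``standardize=True`` residual columns are additionally scaled to unit
    sample standard deviation (using moments learned at fit time).

    Attributes
    ----------
    coef_ : (p+1, q) ndarray
        Confounder regression coefficients (intercept included).
    n_features_in_ : int
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, y=None, *, confounders=None):
        X = np.asarray(X, dtype=float)
        if confounders is None:
            G = np.ones((X.shape[0], 1))
        else:
            G = np.asarray(confounders, dtype=float)
            if G.ndim == 1:
                G = G[:, None]
            G = _add_intercept(G)
        if G.shape[0] != X.shape[0]:
            raise ValueError("X and confounders must have the same number of rows")
        coef, *_ = np.linalg.lstsq(G, X, rcond=None)
        self.coef_ = coef
        self._G_fit = G
        resid = X - G @ coef
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            sd = resid.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("zero-variance residual column")
            self.scale_ = sd
        return self

    def transform(self, X, *, confounders=None):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if confounders is None:
            if X.shape[0] != self._G_fit.shape[0]:
                raise ValueError(
                    "transform on new rows requires their confounders"
                )
            G = self._G_fit
        else:
            G = np.asarray(confounders, dtype=float)
            if G.ndim == 1:
                G = G[:, None]
            G = _add_intercept(G)
        resid = X - G @ self.coef_
        if self.standardize:
            resid = resid / self.scale_
        return resid

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(
            X, confounders=fit_params.get("confounders")
        )
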