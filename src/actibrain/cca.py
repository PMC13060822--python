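"""Bipartial canonical correlation analysis with dual mode inference.

Canonical correlation analysis (CCA) finds paired linear combinations
``U_j = X a_j`` and ``V_j = Y b_j`` of two variable blocks that maximize
their correlation; successive modes are mutually uncorrelated.  "Bipartial"
CCA first residualizes each block on its own confounder set, so the
canonical structure reflects covariation net of nuisance effects.

Mode significance is assessed two ways:

* an asymptotic likelihood-based test — Bartlett's chi-square approximation
  to Wilks' lambda (Rao's F available via ``method="rao"``);
* a permutation test that re-fits CCA after uniformly permuting the rows of
  one residualized block.

Residualization can break row exchangeability, so permutation p-values for
modes beyond the first carry a logged caveat; interpretation is safest for
the primary mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from actibrain.preprocess import residualize_block, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "BipartialCCA",
    "ModeTestReport",
    "approximation_test",
    "cross_loadings",
    "fit_bipartial_cca",
    "fit_cca",
    "permutation_test",
    "variance_explained",
]

#: relative eigenvalue below which within-block covariance directions are
#: treated as null space during whitening
_EIG_RTOL = 1e-10


@dataclass
class ModeTestReport:
    """Per-mode significance report for canonical correlation modes.

    Attributes
    ----------
    method : str
        ``"approximation"`` or ``"permutation"``.
    statistic : ndarray
        Per-mode test statistic (chi-square / F for the approximation test,
        the observed canonical correlation for the permutation test).
    p_values : ndarray
        Per-mode p-values in [0, 1].  Permutation p-values are bounded
        below by ``1 / (n_permutations + 1)``.
    n_permutations : int or None
    seed : int or None
    """

    method: str
    statistic: np.ndarray
    p_values: np.ndarray
    n_permutations: int | None = None
    seed: int | None = None
    df: np.ndarray | None = field(default=None, repr=False)


def _inv_sqrt(C: np.ndarray, rtol: float = _EIG_RTOL) -> np.ndarray:
    """Symmetric inverse square root with spectral truncation.

    Eigenvalues below ``rtol * max(eig)`` are treated as zero (pseudo-
    inverse), making the whitening stable for near-singular within-block
    covariances.
    """
    w, Q = np.linalg.eigh(C)
    thresh = rtol * np.max(w) if w.size else 0.0
    keep = w > thresh
    inv_sqrt_w = np.zeros_like(w)
    inv_sqrt_w[keep] = 1.0 / np.sqrt(w[keep])
    return (Q * inv_sqrt_w) @ Q.T


def _canonical_from_centered(Xc: np.ndarray, Yc: np.ndarray):
    """Canonical correlations/weights of two centered blocks.

    Returns (rho, A, B) with rho descending; weights columns scale the
    variates to unit sample variance (ddof=1).
    """
    n = Xc.shape[0]
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    K = Wx @ Cxy @ Wy
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    k = min(Xc.shape[1], Yc.shape[1])
    s = np.clip(s[:k], 0.0, 1.0)
    A = Wx @ U[:, :k]
    B = Wy @ Vt.T[:, :k]
    # rescale weights so the variates have unit sample variance (whitened
    # pseudo-directions already do, up to truncated-rank effects)
    for j in range(k):
        su = (Xc @ A[:, j]).std(ddof=1)
        sv = (Yc @ B[:, j]).std(ddof=1)
        if su > 0:
            A[:, j] /= su
        if sv > 0:
            B[:, j] /= sv
    return s, A, B


def fit_cca(Xres, Yres):
    """Fit plain CCA on residualized (or at least centered) blocks.

    Thin functional wrapper: returns a fitted :class:`BipartialCCA` with
    intercept-only confounders and no standardization, i.e. classical CCA
    of the centered inputs.
    """
    return BipartialCCA(scale=False).fit(Xres, Yres)


def fit_bipartial_cca(X, Y, Gx=None, Gy=None, *, scale=True):
    """Residualize each block on its own confounders, then fit CCA."""
    return BipartialCCA(scale=scale).fit(X, Y, confounders_x=Gx, confounders_y=Gy)


class BipartialCCA(BaseEstimator):
    """Canonical correlation analysis after per-block confounder removal.

    Each block is residualized on its own confounder matrix (intercept
    always included), optionally standardized to unit column variance
    (``scale=True``, the default: correlation-scale CCA), and the canonical
    structure is computed as the singular value decomposition of the
    whitened cross-covariance.  Near-singular within-block covariances are
    handled by spectral truncation at relative eigenvalue 1e-10.

    Sign convention: each mode is oriented so that the X-side structure
    loading of largest magnitude is positive — canonical signs are
    otherwise arbitrary and a fixed orientation is needed to interpret
    variable/variate correlations.

    Parameters
    ----------
    scale : bool, default True
        Standardize residualized columns to unit sample variance before
        fitting (CCA on the correlation scale).  With ``False`` the fit is
        on the covariance scale.
    n_components : int or None
        Number of modes to retain; default ``min(p, q)``.

    Attributes
    ----------
    rho_ : (k,) ndarray
        Canonical correlations, descending, in [0, 1].
    x_weights_, y_weights_ : (p, k), (q, k) ndarray
        Canonical coefficient vectors (applied to the residualized,
        optionally standardized blocks); variates have unit sample
        variance.
    x_scores_, y_scores_ : (n, k) ndarray
        Canonical variates U, V.
    x_loadings_, y_loadings_ : ndarray
        Structure loadings: correlation of each residualized column with
        its own block's variates.
    n_samples_, n_features_x_, n_features_y_ : int

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> z = rng.standard_normal(500)
    >>> X = np.c_[z, rng.standard_normal(500)] + rng.standard_normal((500, 2))
    >>> Y = np.c_[z, rng.standard_normal(500)] + rng.standard_normal((500, 2))
    >>> cca = BipartialCCA().fit(X, Y)
    >>> cca.rho_.shape
    (2,)
    """

    def __init__(self, scale: bool = True, n_components: int | None = None):
        self.scale = scale
        self.n_components = n_components

    # -- fitting ---------------------------------------------------------

    def fit(self, X, Y, *, confounders_x=None, confounders_y=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-d arrays")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"row mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
            )
        n, p = X.shape
        q = Y.shape[1]
        if n <= max(p, q):
            raise ValueError(
                f"need n > max(p, q); got n={n}, p={p}, q={q}"
            )
        Gx = np.empty((n, 0)) if confounders_x is None else np.asarray(confounders_x, float)
        Gy = np.empty((n, 0)) if confounders_y is None else np.asarray(confounders_y, float)
        if Gx.ndim == 1:
            Gx = Gx[:, None]
        if Gy.ndim == 1:
            Gy = Gy[:, None]
        if Gx.shape[0] != n or Gy.shape[0] != n:
            raise ValueError("confounder matrices must align with data rows")

        self._n_conf_x = Gx.shape[1]
        self._n_conf_y = Gy.shape[1]
        Xr = residualize_block(X, Gx)
        Yr = residualize_block(Y, Gy)
        if self.scale:
            Xr = standardize(Xr)
            Yr = standardize(Yr)
        else:
            sdx = Xr.std(axis=0, ddof=1)
            sdy = Yr.std(axis=0, ddof=1)
            if np.any(sdx <= 0) or np.any(sdy <= 0):
                raise ValueError("zero-variance column in residualized block")

        rho, A, B = _canonical_from_centered(Xr, Yr)
        k = min(p, q) if self.n_components is None else min(self.n_components, p, q)
        rho, A, B = rho[:k], A[:, :k], B[:, :k]
        U = Xr @ A
        V = Yr @ B

        # orient each mode: largest-|.| X-side structure loading positive
        for j in range(k):
            load = _pearson_columns(Xr, U[:, j])
            i_max = int(np.nanargmax(np.abs(load)))
            if load[i_max] < 0:
                A[:, j] *= -1
                B[:, j] *= -1
                U[:, j] *= -1
                V[:, j] *= -1

        self.rho_ = rho
        self.x_weights_ = A
        self.y_weights_ = B
        self.x_scores_ = U
        self.y_scores_ = V
        self.x_residual_ = Xr
        self.y_residual_ = Yr
        self.x_loadings_ = np.column_stack(
            [_pearson_columns(Xr, U[:, j]) for j in range(k)]
        )
        self.y_loadings_ = np.column_stack(
            [_pearson_columns(Yr, V[:, j]) for j in range(k)]
        )
        self.n_samples_ = n
        self.n_features_x_ = p
        self.n_features_y_ = q
        self.n_components_ = k
        return self

    # -- derived quantities ---------------------------------------------

    def variance_explained(self, side: str = "x") -> np.ndarray:
        """Per-mode proportion of within-block variance explained.

        Mode j explains ``sum_l corr(col_l, variate_j)^2 var(col_l) /
        sum_l var(col_l)`` of its own block; summed over all min(p, q)
        modes of the smaller block this is 1 (the variates span the
        block's column space).
        """
        check_is_fitted(self, "rho_")
        if side == "x":
            return variance_explained(self.x_residual_, self.x_scores_)
        if side == "y":
            return variance_explained(self.y_residual_, self.y_scores_)
        raise ValueError("side must be 'x' or 'y'")

    def cross_loadings(self, side: str = "x", mode: int = 0) -> np.ndarray:
        """Correlate each variable of one block with the *other* block's variate.

        ``side='x'`` gives the correlations between the residualized X
        variables and the Y-side variate of the given mode (e.g. PA
        variables against the primary brain canonical variate).
        """
        check_is_fitted(self, "rho_")
        if side == "x":
            return cross_loadings(self.x_residual_, self.y_scores_[:, mode])
        if side == "y":
            return cross_loadings(self.y_residual_, self.x_scores_[:, mode])
        raise ValueError("side must be 'x' or 'y'")

    def approximation_test(self, method: str = "bartlett") -> ModeTestReport:
        """Asymptotic likelihood-based per-mode significance test.

        The sample size entering the approximation is the residual degrees
        of freedom ``n - max(confounder columns per side)``: residualizing
        a block consumes degrees of freedom, and ignoring that loss makes
        the chi-square test anti-conservative.
        """
        check_is_fitted(self, "rho_")
        n_eff = self.n_samples_ - max(self._n_conf_x, self._n_conf_y)
        return approximation_test(
            self.rho_,
            n_eff,
            self.n_features_x_,
            self.n_features_y_,
            method=method,
        )

    def permutation_test(
        self, n_permutations: int = 999, seed: int | None = None
    ) -> ModeTestReport:
        """Permutation per-mode significance test (rows of X permuted)."""
        check_is_fitted(self, "rho_")
        return permutation_test(
            self.x_residual_,
            self.y_residual_,
            n_permutations=n_permutations,
            seed=seed,
            observed_rho=self.rho_,
        )


def _pearson_columns(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with vector v.

    Zero-variance columns yield NaN (with a logged warning) rather than an
    error.
    """
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
    out = np.full(M.shape[1], np.nan)
    ok = denom > 0
    if not np.all(ok):
        logger.warning(
            "zero-variance column(s) %s: loading set to NaN",
            np.flatnonzero(~ok).tolist(),
        )
    out[ok] = (Mc[:, ok].T @ vc) / denom[ok]
    return out


def variance_explained(block_residualized, variates) -> np.ndarray:
    """Proportion of a block's total variance explained by each variate.

    Parameters
    ----------
    block_residualized : (n, q) array-like
    variates : (n, k) array-like
        Unit-variance, mutually uncorrelated canonical variates.

    Returns
    -------
    (k,) ndarray of proportions; on the block's own side the full mode set
    sums to 1.
    """
    B = np.asarray(block_residualized, dtype=float)
    V = np.asarray(variates, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    corr_vv = np.corrcoef(V, rowvar=False)
    if V.shape[1] > 1 and not np.allclose(
        corr_vv - np.eye(V.shape[1]), 0.0, atol=1e-6
    ):
        raise ValueError("variates must be mutually uncorrelated")
    var_cols = B.var(axis=0, ddof=1)
    total = var_cols.sum()
    out = np.empty(V.shape[1])
    for j in range(V.shape[1]):
        r = _pearson_columns(B, V[:, j])
        out[j] = np.nansum(r**2 * var_cols) / total
    return out


def cross_loadings(block_residualized, variate) -> np.ndarray:
    """Pearson correlation of each block column with a canonical variate."""
    B = np.asarray(block_residualized, dtype=float)
    v = np.asarray(variate, dtype=float).ravel()
    if B.shape[0] != v.shape[0]:
        raise ValueError("variate length must match block rows")
    return _pearson_columns(B, v)


def approximation_test(rho, n, p, q, *, method: str = "bartlett") -> ModeTestReport:
    """Likelihood-based significance of canonical modes.

    For mode ``s`` (1-based), Wilks' lambda ``Lambda_s = prod_{j>=s}
    (1 - rho_j^2)`` is tested.  ``method="bartlett"`` uses Bartlett's
    chi-square approximation: statistic ``-(n - 1 - (p + q + 1)/2) *
    log(Lambda_s)`` with ``(p - s + 1)(q - s + 1)`` degrees of freedom.
    ``method="rao"`` uses Rao's F approximation.

    Parameters
    ----------
    rho : (k,) array-like
        Canonical correlations, all strictly below 1.
    n, p, q : int
        Sample size and block widths; requires ``n > p + q``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho >= 1.0):
        raise ValueError("degenerate canonical correlation rho >= 1")
    if n <= p + q:
        raise ValueError(f"approximation test requires n > p + q (n={n})")
    k = rho.shape[0]
    one_minus = 1.0 - rho**2
    stats_out = np.empty(k)
    pvals = np.empty(k)
    dfs = np.empty(k)
    for s in range(1, k + 1):
        log_lambda = np.sum(np.log(one_minus[s - 1 :]))
        df_num = (p - s + 1) * (q - s + 1)
        dfs[s - 1] = df_num
        if method == "bartlett":
            c = n - 1 - (p + q + 1) / 2.0
            chi2 = -c * log_lambda
            stats_out[s - 1] = chi2
            pvals[s - 1] = stats.chi2.sf(chi2, df_num)
        elif method == "rao":
            ps, qs = p - s + 1, q - s + 1
            lam = np.exp(log_lambda)
            m = n - 1 - (ps + qs + 1) / 2.0
            denom = ps**2 + qs**2 - 5
            t = (
                np.sqrt((ps**2 * qs**2 - 4) / denom)
                if denom > 0
                else 1.0
            )
            df2 = m * t - df_num / 2.0 + 1.0
            lam_t = lam ** (1.0 / t)
            F = (1.0 - lam_t) / lam_t * df2 / df_num
            stats_out[s - 1] = F
            pvals[s - 1] = stats.f.sf(F, df_num, df2)
        else:
            raise ValueError("method must be 'bartlett' or 'rao'")
    return ModeTestReport(
        method="approximation", statistic=stats_out, p_values=pvals, df=dfs
    )


def permutation_test(
    Xres,
    Yres,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    observed_rho=None,
) -> ModeTestReport:
    """Permutation significance of canonical modes.

    Rows of the X block (by design the smaller, PA-like side) are permuted
    uniformly; canonical correlations are recomputed for each draw, and the
    per-mode p-value is ``(1 + #{rho*_j >= rho_hat_j}) / (n_permutations +
    1)``.

    Residualized rows may not be exchangeable, which can bias p-values for
    modes beyond the first; a warning is logged and interpretation should
    focus on the primary mode.

    Parameters
    ----------
    Xres, Yres : residualized blocks, row-aligned.
    n_permutations : int, >= 99 (p-value resolution).
    seed : int or None
    observed_rho : optional pre-computed observed canonical correlations.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99 for usable p-value resolution")
    Xres = np.asarray(Xres, dtype=float)
    Yres = np.asarray(Yres, dtype=float)
    if observed_rho is None:
        observed_rho, _, _ = _canonical_from_centered(
            Xres - Xres.mean(0), Yres - Yres.mean(0)
        )
    observed_rho = np.asarray(observed_rho, dtype=float)
    k = observed_rho.shape[0]
    if k > 1:
        logger.warning(
            "permutation p-values for modes beyond the first may be "
            "anti-conservative: residualized rows are not exactly exchangeable"
        )
    rng = np.random.default_rng(seed)
    n = Xres.shape[0]
    exceed = np.zeros(k, dtype=int)
    Xc = Xres - Xres.mean(0)
    Yc = Yres - Yres.mean(0)
    # whiten each block once: permuting rows of a whitened block leaves it
    # whitened, so each draw only needs the SVD of the p x q cross-product
    Xw = Xc @ _inv_sqrt(Xc.T @ Xc / (n - 1))
    Yw = Yc @ _inv_sqrt(Yc.T @ Yc / (n - 1))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        s = np.linalg.svd(Xw[perm].T @ Yw / (n - 1), compute_uv=False)
        rho_star = np.clip(s[:k], 0.0, 1.0)
        exceed += rho_star >= observed_rho
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    return ModeTestReport(
        method="permutation",
        statistic=observed_rho,
        p_values=pvals,
        n_permutations=n_permutations,
        seed=seed,
    )
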