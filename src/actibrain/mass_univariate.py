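"""Mass-univariate PA-to-phenotype association and variable importance.

Each of q phenotype columns (functional-connectivity edges or regional
volumes) is regressed on confounders G plus the 11 PA variables H.
Significance of the PA block is assessed per response by a partial F-test
(confounders-only vs confounders + PA), with Benjamini-Hochberg control of
the false discovery rate across the q responses; the surviving index set is
the "screened" set of responses.  Predictive value is summarized by the
mean Pearson correlation between observed and out-of-fold predicted
responses over repeated 10-fold cross-validation.

Three engines score the importance of individual PA variables:

* t-tests on PA coefficients in the full linear model (-log10 p);
* bidirectional stepwise search over PA variables by BIC, confounders
  forced into every candidate model (0/1 selection);
* random-forest permutation importance on [G H], reported for the PA
  columns only.

A consensus ranking averages rank-normalized per-method scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceTable",
    "MassUnivariateResult",
    "MassUnivariateScreen",
    "bh_select",
    "consensus_ranking",
    "cv_predictive_correlation",
    "importance_random_forest",
    "importance_stepwise_bic",
    "importance_ttest",
    "screen_responses",
]


def bh_select(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up selection and adjusted p-values.

    Returns
    -------
    (reject, p_adjusted) boolean and float arrays of the input length.
    """
    reject, p_adj, *_ = multipletests(
        np.asarray(pvals, dtype=float), alpha=alpha, method="fdr_bh"
    )
    return reject, p_adj


@dataclass
class MassUnivariateResult:
    """Per-response screening output."""

    p_values: np.ndarray  # raw partial-F p-values, length q
    p_adjusted: np.ndarray  # BH-adjusted
    selected: np.ndarray  # index set J (adjusted p <= alpha)
    alpha: float
    f_statistics: np.ndarray = field(default=None, repr=False)
    cv_correlation: np.ndarray | None = None  # per-response mean CV corr
    n_reps: int | None = None
    seed: int | None = None


@dataclass
class ImportanceTable:
    """Responses x PA-variables importance scores.

    ``method`` fixes the score semantics: ``ttest`` stores -log10 p,
    ``stepwise_bic`` 0/1 selection indicators, ``random_forest``
    permutation-importance scores.
    """

    scores: pd.DataFrame
    method: str


def _check_design(G, H, n):
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if H.ndim == 1:
        H = H[:, None]
    if G.shape[0] != n or H.shape[0] != n:
        raise ValueError("G and H must align with the response rows")
    ones = np.ones((n, 1))
    G = np.hstack([ones, G])
    X = np.hstack([G, H])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name offending columns by greedy QR-based detection
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(R[0, 0]))
        raise ValueError(
            f"[G H] design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column indices (incl. intercept at 0): {bad.tolist()}"
        )
    return G, H, X


def _rss_columns(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of each Y column regressed on X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef
    return (R**2).sum(axis=0)


def screen_responses(
    Y, G, H, alpha: float = 0.05, test: str = "partial"
) -> MassUnivariateResult:
    """F-test of the PA block per response, with BH control.

    With ``test="partial"`` (default) each response's reduced model
    (intercept + confounders) is compared with the full model (+ PA
    variables) — significance of PA *after controlling for confounders*.
    ``test="overall"`` instead tests the full model against the intercept
    alone.  The q p-values are Benjamini-Hochberg adjusted and the index
    set ``{l : adjusted p_l <= alpha}`` is returned.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    G1, H, X = _check_design(G, H, n)
    p_full = X.shape[1]
    df_resid = n - p_full
    if df_resid <= 0:
        raise ValueError("not enough rows for the full design")
    if test == "partial":
        rss0 = _rss_columns(G1, Y)
        df_num = H.shape[1]
    elif test == "overall":
        rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        df_num = p_full - 1
    else:
        raise ValueError("test must be 'partial' or 'overall'")
    rss1 = _rss_columns(X, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_num) / (rss1 / df_resid)
    F = np.where(rss1 <= 0, np.inf, F)
    pvals = stats.f.sf(F, df_num, df_resid)
    reject, p_adj = bh_select(pvals, alpha)
    return MassUnivariateResult(
        p_values=pvals,
        p_adjusted=p_adj,
        selected=np.flatnonzero(reject),
        alpha=alpha,
        f_statistics=F,
    )


def cv_predictive_correlation(
    y, X, n_folds: int = 10, n_reps: int = 100, seed: int | None = None
):
    """Mean out-of-fold Pearson correlation over repeated K-fold CV.

    Per repetition a fresh shuffled K-fold split of the rows is drawn; a
    linear model is fit on each training fold and its held-out predictions
    are assembled into a full predicted vector, whose Pearson correlation
    with the observed response is recorded.  Repetitions with constant
    out-of-fold predictions are recorded as NaN with a warning.

    Returns
    -------
    (mean_correlation, per_rep_correlations)
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if n < 2 * n_folds:
        raise ValueError("need n >= 2 * n_folds")
    X1 = np.hstack([np.ones((n, 1)), X])
    ss = np.random.SeedSequence([0 if seed is None else seed, 411])
    rep_seeds = ss.generate_state(n_reps)
    per_rep = np.empty(n_reps)
    for r in range(n_reps):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rep_seeds[r] % (2**31)))
        yhat = np.empty(n)
        for tr, te in kf.split(X1):
            coef, *_ = np.linalg.lstsq(X1[tr], y[tr], rcond=None)
            yhat[te] = X1[te] @ coef
        if np.std(yhat) == 0 or np.std(y) == 0:
            logger.warning("constant predictions in repetition %d: NaN", r)
            per_rep[r] = np.nan
        else:
            per_rep[r] = np.corrcoef(y, yhat)[0, 1]
    return float(np.nanmean(per_rep)), per_rep


def importance_ttest(Y, G, H, pa_names=None) -> ImportanceTable:
    """-log10 p of each PA coefficient's t-test, per response.

    Every model includes intercept + confounders + all PA variables; the
    same design is shared across responses, so standard errors reuse one
    (X'X)^{-1} factor.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    G1, H, X = _check_design(G, H, n)
    p2 = H.shape[1]
    df_resid = n - X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y
    resid = Y - X @ coef
    sigma2 = (resid**2).sum(axis=0) / df_resid
    pa_slice = slice(X.shape[1] - p2, X.shape[1])
    se = np.sqrt(np.outer(np.diag(XtX_inv)[pa_slice], sigma2))
    tstat = coef[pa_slice] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    scores = -np.log10(np.clip(pvals, 1e-300, None)).T  # q x p2
    names = pa_names if pa_names is not None else [f"PA{j+1}" for j in range(p2)]
    return ImportanceTable(
        scores=pd.DataFrame(scores, columns=names), method="ttest"
    )


def _bic(n: int, rss: float, k: int) -> float:
    return n * np.log(rss / n) + k * np.log(n)


def importance_stepwise_bic(Y, G, H, pa_names=None) -> ImportanceTable:
    """Bidirectional stepwise selection of PA variables by BIC.

    The search starts from the confounders-only model and at each step
    considers adding any excluded PA variable or dropping any included
    one, taking the move with the best BIC improvement (ties broken by
    first candidate in fixed column order); confounders are forced into
    every model.  Deterministic given the data.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    G1, H, _ = _check_design(G, H, n)
    p2 = H.shape[1]
    sel_all = np.zeros((q, p2), dtype=int)
    for l in range(q):
        y = Y[:, l]
        included: list[int] = []
        rss_cur = _rss_columns(G1, y[:, None])[0]
        bic_cur = _bic(n, rss_cur, G1.shape[1])
        improved = True
        while improved:
            improved = False
            best = (bic_cur, None, None)  # (bic, action, var)
            for j in range(p2):
                if j in included:
                    cand = [c for c in included if c != j]
                    action = "drop"
                else:
                    cand = included + [j]
                    action = "add"
                Xc = np.hstack([G1, H[:, cand]]) if cand else G1
                rss = _rss_columns(Xc, y[:, None])[0]
                bic = _bic(n, rss, Xc.shape[1])
                if bic < best[0] - 1e-10:
                    best = (bic, action, j)
            if best[1] is not None:
                bic_cur = best[0]
                if best[1] == "add":
                    included.append(best[2])
                else:
                    included.remove(best[2])
                improved = True
        sel_all[l, included] = 1
    names = pa_names if pa_names is not None else [f"PA{j+1}" for j in range(p2)]
    return ImportanceTable(
        scores=pd.DataFrame(sel_all, columns=names), method="stepwise_bic"
    )


def importance_random_forest(
    Y,
    G,
    H,
    n_trees: int = 100,
    seed: int | None = None,
    pa_names=None,
    n_permutation_repeats: int = 5,
) -> ImportanceTable:
    """Random-forest permutation importance of PA variables, per response.

    A regression forest is fit on [G H] for each response; permutation
    importance (mean decrease in R^2 when a column is shuffled) is
    computed on the training data and reported for the PA columns only.
    Degenerate (constant) responses are skipped with a warning.
    """
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    H = np.asarray(H, dtype=float)
    X = np.hstack([G, H])
    p2 = H.shape[1]
    pa_idx = np.arange(G.shape[1], X.shape[1])
    ss = np.random.SeedSequence([0 if seed is None else seed, 95])
    col_seeds = ss.generate_state(2 * q)
    out = np.full((q, p2), np.nan)
    for l in range(q):
        y = Y[:, l]
        if np.std(y) == 0:
            logger.warning("response %d is constant: skipped", l)
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(col_seeds[2 * l] % (2**31)),
            n_jobs=1,
        ).fit(X, y)
        imp = permutation_importance(
            rf,
            X,
            y,
            n_repeats=n_permutation_repeats,
            random_state=int(col_seeds[2 * l + 1] % (2**31)),
            n_jobs=1,
        )
        out[l] = imp.importances_mean[pa_idx]
    names = pa_names if pa_names is not None else [f"PA{j+1}" for j in range(p2)]
    return ImportanceTable(
        scores=pd.DataFrame(out, columns=names), method="random_forest"
    )


def consensus_ranking(tables: list[ImportanceTable]) -> pd.DataFrame:
    """Cross-method consensus ranking of PA variables.

    Per method, column-mean scores are converted to ranks (1 = most
    important) and the per-method ranks averaged; the result is sorted by
    mean rank with per-method ranks attached.
    """
    if len(tables) < 2:
        raise ValueError("need at least two importance tables")
    cols = list(tables[0].scores.columns)
    for t in tables[1:]:
        if list(t.scores.columns) != cols:
            raise ValueError("importance tables have mismatched PA columns")
    ranks = {}
    for t in tables:
        mean_score = t.scores.mean(axis=0)
        ranks[t.method] = mean_score.rank(ascending=False, method="average")
    rank_df = pd.DataFrame(ranks)
    rank_df["mean_rank"] = rank_df.mean(axis=1)
    return rank_df.sort_values("mean_rank")


class MassUnivariateScreen(BaseEstimator):
    """Estimator bundling screening, CV prediction and importance engines.

    ``fit(Y, confounders=G, pa=H)`` runs the partial-F screen with BH
    control; ``cv_correlations`` and the importance methods operate on the
    screened (or all) responses.

    Parameters
    ----------
    alpha : float
        BH false-discovery-rate level (default 0.05).
    n_folds, n_reps : int
        Repeated-CV settings for predictive correlations.
    seed : int or None

    Attributes
    ----------
    result_ : MassUnivariateResult
    selected_ : ndarray of screened response indices.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_folds: int = 10,
        n_reps: int = 100,
        seed: int | None = None,
    ):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_reps = n_reps
        self.seed = seed

    def fit(self, Y, y=None, *, confounders, pa):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.result_ = screen_responses(Y, confounders, pa, alpha=self.alpha)
        self.selected_ = self.result_.selected
        self._Y = Y
        self._G = np.asarray(confounders, dtype=float)
        self._H = np.asarray(pa, dtype=float)
        if self._G.ndim == 1:
            self._G = self._G[:, None]
        if self._H.ndim == 1:
            self._H = self._H[:, None]
        return self

    def cv_correlations(
        self, responses=None, *, predictors: str = "confounders+pa"
    ) -> np.ndarray:
        """Mean repeated-CV predictive correlation per (screened) response.

        ``predictors`` selects the design: confounders+PA (default,
        matching the screening design) or ``"pa"`` only.
        """
        check_is_fitted(self, "result_")
        idx = self.selected_ if responses is None else np.asarray(responses)
        if predictors == "confounders+pa":
            X = np.hstack([self._G, self._H])
        elif predictors == "pa":
            X = self._H
        else:
            raise ValueError("predictors must be 'confounders+pa' or 'pa'")
        out = np.empty(idx.shape[0])
        for i, l in enumerate(idx):
            out[i], _ = cv_predictive_correlation(
                self._Y[:, l],
                X,
                n_folds=self.n_folds,
                n_reps=self.n_reps,
                seed=None if self.seed is None else self.seed + int(l),
            )
        self.result_.cv_correlation = out
        self.result_.n_reps = self.n_reps
        self.result_.seed = self.seed
        return out

    def importance(
        self, method: str, responses=None, pa_names=None, n_trees: int = 100
    ) -> ImportanceTable:
        """Run one importance engine on the screened (or given) responses.

        The random forest uses all responses by default, mirroring its use
        as a model-free engine; t-test and stepwise operate on the
        screened set.
        """
        check_is_fitted(self, "result_")
        if responses is None:
            idx = (
                np.arange(self._Y.shape[1])
                if method == "random_forest"
                else self.selected_
            )
        else:
            idx = np.asarray(responses)
        Ysub = self._Y[:, idx]
        if method == "ttest":
            tab = importance_ttest(Ysub, self._G, self._H, pa_names=pa_names)
        elif method == "stepwise_bic":
            tab = importance_stepwise_bic(
                Ysub, self._G, self._H, pa_names=pa_names
            )
        elif method == "random_forest":
            tab = importance_random_forest(
                Ysub,
                self._G,
                self._H,
                n_trees=n_trees,
                seed=self.seed,
                pa_names=pa_names,
            )
        else:
            raise ValueError(
                "method must be 'ttest', 'stepwise_bic' or 'random_forest'"
            )
        tab.scores.index = pd.Index(idx, name="response")
        return tab
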