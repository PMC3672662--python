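"""Motif Activity Response Analysis (MARA).

Log-expression of every gene is modeled as a linear combination of
transcription-factor motif activities, with coefficients given by the
number of predicted binding sites in the proximal promoter:

    E_gs ~ sum_m N_gm * A_ms + noise

After double-centering the expression matrix (per gene and per sample)
and column-centering the site counts, the per-sample activities A_.s are
the ridge solution (N'N + lambda I)^-1 N' E_.s, with standard errors
from the residual variance and the diagonal of the ridge inverse.  The
penalty counters the near-collinearity of site counts for related
motifs; it can be fixed or chosen by gene-wise cross-validation.
Condition contrasts (parous vs virgin) are scored per motif by a z
statistic on the difference of mean activities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, SiteCountMatrix

__all__ = ["MotifActivityModel", "fit_activities", "motif_change_z"]

_DEFAULT_GRID = tuple(np.logspace(-3.0, 3.0, 13))


def _prepare(expr: ExpressionMatrix, sites: SiteCountMatrix):
    shared = expr.values_frame.index.intersection(sites.values_frame.index)
    if len(shared) == 0:
        raise ValueError("expression and site-count matrices share no genes")
    E = expr.values_frame.loc[shared].to_numpy(float)
    N = sites.values_frame.loc[shared].to_numpy(float)
    # double-center expression: remove gene baselines and sample offsets
    E = E - E.mean(axis=1, keepdims=True)
    E = E - E.mean(axis=0, keepdims=True)
    N = N - N.mean(axis=0, keepdims=True)
    return shared, E, N


def _ridge_solve(N: np.ndarray, E: np.ndarray, lam: float):
    G, M = N.shape
    gram = N.T @ N + lam * np.eye(M)
    if lam == 0:
        # refuse exactly singular systems rather than pseudo-inverting
        if np.linalg.matrix_rank(N.T @ N) < M:
            raise np.linalg.LinAlgError(
                "N'N is singular (e.g. a motif without sites); use lambda > 0"
            )
    inv = np.linalg.inv(gram)
    A = inv @ N.T @ E
    resid = E - N @ A
    # effective model size per sample: trace of the ridge hat matrix
    df_model = float(np.trace(N @ inv @ N.T))
    df_resid = max(G - df_model, 1.0)
    sigma2 = (resid**2).sum(axis=0) / df_resid  # per sample
    se = np.sqrt(np.outer(np.diag(inv), sigma2) * 1.0)  # motif x sample
    # guard against exactly-zero SE for degenerate motifs
    return A, np.maximum(se, 1e-300), sigma2


class MotifActivityModel(BaseEstimator):
    """Ridge-regularised inference of motif activities per sample.

    Parameters
    ----------
    ridge_lambda : nonnegative penalty, or ``"cv"`` to choose it by
        gene-wise k-fold cross-validation over ``cv_grid``.
    cv_folds, cv_grid, cv_seed : cross-validation design; folds are
        drawn from a seeded generator so fits are reproducible.

    Attributes (after :meth:`fit`)
    ------------------------------
    activities_ : motif x sample activity frame.
    se_ : matching standard-error frame.
    lambda_ : penalty actually used.
    residual_variance_ : mean per-sample residual variance.
    zero_site_motifs_ : motifs with no binding sites (activities not
        identifiable at lambda=0; reported, not dropped).
    """

    def __init__(
        self,
        ridge_lambda: float | str = "cv",
        cv_folds: int = 5,
        cv_grid: tuple[float, ...] = _DEFAULT_GRID,
        cv_seed: int = 0,
    ):
        self.ridge_lambda = ridge_lambda
        self.cv_folds = cv_folds
        self.cv_grid = cv_grid
        self.cv_seed = cv_seed

    def fit(self, expr: ExpressionMatrix, sites: SiteCountMatrix) -> "MotifActivityModel":
        if expr.values_frame.shape[1] < 2:
            raise ValueError("need at least two samples")
        shared, E, N = _prepare(expr, sites)
        motifs = list(sites.values_frame.columns)
        self.zero_site_motifs_ = sites.zero_motifs
        if self.ridge_lambda == "cv":
            lam = self._cross_validate(E, N)
        else:
            lam = float(self.ridge_lambda)
            if lam < 0:
                raise ValueError("ridge_lambda must be nonnegative")
        A, se, sigma2 = _ridge_solve(N, E, lam)
        cols = expr.samples
        self.activities_ = pd.DataFrame(A, index=motifs, columns=cols)
        self.se_ = pd.DataFrame(se, index=motifs, columns=cols)
        self.lambda_ = lam
        self.residual_variance_ = float(np.mean(sigma2))
        self.conditions_ = expr.conditions.copy()
        self.n_shared_genes_ = len(shared)
        return self

    def _cross_validate(self, E: np.ndarray, N: np.ndarray) -> float:
        G = N.shape[0]
        rng = np.random.default_rng(self.cv_seed)
        folds = rng.permutation(G) % self.cv_folds
        best_lam, best_err = None, np.inf
        for lam in self.cv_grid:
            if lam == 0 and np.linalg.matrix_rank(N.T @ N) < N.shape[1]:
                continue
            err = 0.0
            for k in range(self.cv_folds):
                tr, te = folds != k, folds == k
                Ak, _, _ = _ridge_solve(N[tr], E[tr], float(lam))
                err += float(((E[te] - N[te] @ Ak) ** 2).sum())
            if err < best_err:
                best_lam, best_err = float(lam), err
        return best_lam

    def change_report(self, conditions: pd.Series | None = None) -> pd.DataFrame:
        """Per-motif activity change between the two conditions."""
        cond = self.conditions_ if conditions is None else conditions
        return motif_change_z(self.activities_, self.se_, cond)


def fit_activities(
    expr: ExpressionMatrix,
    sites: SiteCountMatrix,
    ridge_lambda: float | str = "cv",
    **kwargs,
) -> MotifActivityModel:
    """Fit motif activities; see :class:`MotifActivityModel`."""
    return MotifActivityModel(ridge_lambda=ridge_lambda, **kwargs).fit(expr, sites)


def motif_change_z(
    activities: pd.DataFrame,
    se: pd.DataFrame,
    conditions: pd.Series,
    contrast: tuple[str, str] = ("virgin", "parous"),
) -> pd.DataFrame:
    """Score per-motif activity change between conditions.

    delta is the mean activity under ``contrast[1]`` minus the mean
    under ``contrast[0]``.  Its standard error combines the
    between-sample spread of fitted activities (which already carries
    the fitting noise, and is moderated across motifs by empirical
    Bayes to stabilise it at few replicates) with the propagated
    per-sample fitting errors, taking whichever is larger so degenerate
    motifs keep a positive SE.  z = delta / SE with a two-sided normal
    p; motifs are returned ranked by |z|.
    """
    ref, alt = contrast
    conditions = conditions.reindex(activities.columns)
    for label in (ref, alt):
        if not (conditions == label).any():
            raise ValueError(f"condition {label!r} has no samples")
    a = activities.loc[:, conditions == ref].to_numpy(float)
    b = activities.loc[:, conditions == alt].to_numpy(float)
    se_a = se.loc[:, conditions == ref].to_numpy(float)
    se_b = se.loc[:, conditions == alt].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    delta = b.mean(axis=1) - a.mean(axis=1)
    if na > 1 and nb > 1:
        pooled = (
            ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ) / (na + nb - 2)
        # at a handful of replicates the per-motif spread is itself very
        # noisy; shrink it across motifs by the same empirical-Bayes
        # moderation used for gene variances before forming z
        if len(pooled) >= 3 and np.any(pooled > 0):
            from .diffexpr import estimate_variance_prior

            d0, s0_sq = estimate_variance_prior(pooled, na + nb - 2)
            dg = na + nb - 2
            if np.isinf(d0):
                pooled = np.full_like(pooled, s0_sq)
            else:
                pooled = (d0 * s0_sq + dg * pooled) / (d0 + dg)
    else:
        pooled = np.zeros(a.shape[0])
    fit_var = 0.5 * (se_a**2).mean(axis=1) + 0.5 * (se_b**2).mean(axis=1)
    var = np.maximum(pooled, fit_var) * (1.0 / na + 1.0 / nb)
    if np.any(var <= 0):
        warnings.warn("motifs with zero variance; z set to 0", RuntimeWarning, stacklevel=2)
    z = np.where(var > 0, delta / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    report = pd.DataFrame(
        {"delta_activity": delta, "z": z, "p": p}, index=activities.index
    )
    return report.loc[np.abs(report["z"]).sort_values(ascending=False).index]
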