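"""Moderated two-group differential expression on log2 matrices.

Gene-wise residual variances are shrunk toward a pooled prior by
empirical Bayes before forming t-statistics, which stabilises inference
at the small replicate numbers typical of sorted-cell microarray
experiments (here three arrays per donor group).  The prior is an
inverse-chi-square with (d0, s0^2) estimated by the method of moments on
log residual variances; the shrunken variance is

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and the moderated t has d0 + d_g degrees of freedom.  Downstream filters
apply the study's cutoffs (linear fold change, BH-adjusted p, average
linear expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "FilterCriteria",
    "ModeratedTTest",
    "zscore_rows",
    "moderated_t",
    "apply_filters",
    "top_genes",
    "collapse_probes",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Retention cutoffs for a differential-expression table.

    min_linear_fc : keep genes with 2^|log2FC| strictly above this.
    max_p_adj : keep genes with adjusted p strictly below this.
    min_ave_linear_expr : keep genes whose mean linear-scale expression
        across the two conditions is strictly above this.
    """

    min_linear_fc: float = 1.5
    max_p_adj: float = 0.05
    min_ave_linear_expr: float = 4.0

    def __post_init__(self) -> None:
        if self.min_linear_fc <= 1:
            raise ValueError("min_linear_fc must exceed 1")
        if not 0 < self.max_p_adj < 1:
            raise ValueError("max_p_adj must lie in (0, 1)")
        if self.min_ave_linear_expr <= 0:
            raise ValueError("min_ave_linear_expr must be positive")


def zscore_rows(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Row-standardise a gene x sample matrix: Z = (x - mean) / sd.

    Sample standard deviation (ddof=1).  Constant rows map to all zeros
    with a warning.
    """
    values = matrix.values_frame if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least two samples per row")
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) mapped to all-zero z-scores",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = sd.where(~constant, 1.0)
    out = values.sub(mu, axis=0).div(safe_sd, axis=0)
    out.loc[constant] = 0.0
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior.

    Matches the mean and variance of log s_g^2 against the theoretical
    moments of a scaled F-distributed sample variance.  Returns
    (inf, exp(mean adjusted)) when the observed spread is no larger than
    sampling noise, i.e. complete pooling.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene variances to fit the prior")
    z = np.log(s2[ok])
    e = z - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df_resid / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test, gene by gene.

    Parameters
    ----------
    prior_df : ``"auto"`` estimates (d0, s0^2) from the data; a float
        forces that prior df (0 reduces to the ordinary pooled t,
        ``numpy.inf`` pools all genes to one variance).
    prior_scale : only used when ``prior_df`` is numeric; ``"auto"``
        then takes s0^2 from the moment fit (or the mean variance when
        prior_df is forced).

    After :meth:`fit`, ``results_`` holds a frame indexed by gene with
    columns log2_fc (second condition minus first), ave_linear_expr,
    t, p, p_adj, df_total; ``d0_`` and ``s0_sq_`` hold the prior.
    """

    def __init__(self, prior_df: float | str = "auto", prior_scale: float | str = "auto"):
        self.prior_df = prior_df
        self.prior_scale = prior_scale

    def fit(self, X, y=None, *, contrast: tuple[str, str] | None = None) -> "ModeratedTTest":
        """Fit from an :class:`ExpressionMatrix`, or from an array
        (samples x genes) with condition labels ``y``."""
        if isinstance(X, ExpressionMatrix):
            expr = X
        else:
            Xa = np.asarray(X, float)
            if y is None:
                raise ValueError("condition labels y are required for array input")
            genes = [f"g{i}" for i in range(Xa.shape[1])]
            samples = [f"s{i}" for i in range(Xa.shape[0])]
            expr = ExpressionMatrix(
                pd.DataFrame(Xa.T, index=genes, columns=samples),
                pd.Series(list(y), index=samples),
            )
        if contrast is None:
            levels = list(pd.unique(expr.conditions))
            if len(levels) != 2:
                raise ValueError("exactly two condition levels are required")
            # conventional direction: treated (parous) minus control (virgin)
            if set(levels) == {"virgin", "parous"}:
                contrast = ("virgin", "parous")
            else:
                contrast = (levels[0], levels[1])
        ref, alt = contrast
        A = expr.values_frame.loc[:, expr.conditions == ref].to_numpy(float)
        B = expr.values_frame.loc[:, expr.conditions == alt].to_numpy(float)
        na, nb = A.shape[1], B.shape[1]
        if na < 2 or nb < 2:
            raise ValueError("need >= 2 samples per condition")
        df_resid = na + nb - 2
        mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
        log2_fc = mean_b - mean_a
        ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
        s2 = ss / df_resid

        if self.prior_df == "auto":
            d0, s0_sq = estimate_variance_prior(s2, df_resid)
            pooled_flag = np.isinf(d0)
        else:
            d0 = float(self.prior_df)
            if d0 < 0:
                raise ValueError("prior_df must be nonnegative")
            if self.prior_scale == "auto":
                s0_sq = float(np.mean(s2)) if d0 > 0 else 0.0
            else:
                s0_sq = float(self.prior_scale)
            pooled_flag = np.isinf(d0)
        if pooled_flag:
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2
            df_total = float(df_resid)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = float(d0 + df_resid)
        if np.any(s2_post <= 0):
            raise ValueError("zero posterior variance; residual df exhausted")

        t = log2_fc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        p_adj = multipletests(p, method="fdr_bh")[1]
        ave_linear = 0.5 * (np.exp2(A).mean(axis=1) + np.exp2(B).mean(axis=1))

        self.d0_ = d0
        self.s0_sq_ = s0_sq
        self.fully_pooled_ = bool(pooled_flag)
        self.contrast_ = (ref, alt)
        self.results_ = pd.DataFrame(
            {
                "log2_fc": log2_fc,
                "ave_linear_expr": ave_linear,
                "t": t,
                "p": p,
                "p_adj": p_adj,
                "df_total": df_total,
            },
            index=expr.values_frame.index,
        )
        return self

    def transform(self, X=None) -> pd.DataFrame:
        return self.results_


def moderated_t(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str] = ("virgin", "parous"),
    prior_df: float | str = "auto",
) -> pd.DataFrame:
    """Per-gene moderated t table; log2_fc is ``contrast[1] - contrast[0]``."""
    return ModeratedTTest(prior_df=prior_df).fit(matrix, contrast=contrast).results_


def apply_filters(result: pd.DataFrame, criteria: FilterCriteria) -> list[str]:
    """Genes passing fold-change, adjusted-p and expression cutoffs, in order."""
    keep = (
        (np.exp2(np.abs(result["log2_fc"])) > criteria.min_linear_fc)
        & (result["p_adj"] < criteria.max_p_adj)
        & (result["ave_linear_expr"] > criteria.min_ave_linear_expr)
    )
    return list(result.index[keep])


def top_genes(
    result: pd.DataFrame,
    n: int,
    strict: FilterCriteria = FilterCriteria(2.0, 0.001, 4.0),
) -> tuple[list[str], list[str]]:
    """Top up- and downregulated shortlists under stringent criteria.

    Genes passing ``strict`` are ranked by |log2 fold change| with ties
    broken by adjusted p; the ``n`` strongest in each direction are
    returned as (up, down).
    """
    passing = result.loc[apply_filters(result, strict)]
    ranked = passing.assign(_abs=np.abs(passing["log2_fc"])).sort_values(
        ["_abs", "p_adj"], ascending=[False, True]
    )
    up = list(ranked.index[ranked["log2_fc"] > 0][:n])
    down = list(ranked.index[ranked["log2_fc"] < 0][:n])
    return up, down


def collapse_probes(result: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level table to genes, keeping per gene the probe
    with the largest |log2 fold change|."""
    genes = probe_to_gene.reindex(result.index)
    if genes.isna().any():
        raise ValueError("every probe needs a gene assignment")
    order = np.abs(result["log2_fc"]).sort_values(ascending=False).index
    collapsed = result.loc[order].groupby(genes.loc[order], sort=False).head(1)
    return collapsed.set_index(genes.loc[collapsed.index])
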