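"""Two-group differential expression with empirical-Bayes moderated t.

Per-gene pooled variances are shrunk toward a prior fitted to the whole
variance distribution by method-of-moments on log variances (the classic
limma-style scaled-F model), yielding a moderated t-statistic with
``d0 + d`` degrees of freedom.  Benjamini-Hochberg step-up correction is
applied across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, Scale

__all__ = [
    "DEResult",
    "moderated_ttest",
    "bh_adjust",
    "significant_genes",
    "fit_variance_prior",
]

_DF_CAP = 1e6  # stands in for an infinite prior df


@dataclass
class DEResult:
    """Per-gene differential expression table (group A minus group B).

    ``table`` columns: log2fc, t, p, p_adj, s2, s2_post.  ``prior_df`` and
    ``prior_var`` are the fitted empirical-Bayes hyperparameters; ``df_total``
    is the residual plus prior degrees of freedom used for p-values.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    df_residual: float

    @property
    def df_total(self) -> float:
        return self.df_residual + self.prior_df


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, limma-style)."""
    if y <= 0:
        return _DF_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (prior_df, prior_var) of a scaled-F model to sample variances.

    Matches mean and variance of ``log s2`` to the moments implied by
    ``s2 ~ prior_var * F(df, prior_df)``.  Genes with zero variance are
    excluded from the fit.  Returns ``prior_df`` capped at 1e6 when the
    observed spread is no larger than expected under equal variances.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return _DF_CAP, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        d0 = min(d0, _DF_CAP)
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = _DF_CAP
        s02 = float(np.exp(e_mean))
    return d0, s02


def moderated_ttest(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated two-sample t-test per gene, group A vs group B.

    ``log2fc`` is the difference of group means on the log2(TPM+1) scale.
    ``prior_df`` overrides the fitted prior degrees of freedom; ``0`` gives
    the ordinary pooled two-sample t-test.
    """
    if expr.scale is not Scale.LOG2_TPM_PLUS1:
        raise ValueError("moderated_ttest expects log-scale expression")
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = expr.data[group_a].to_numpy()
    xb = expr.data[group_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    df = na + nb - 2

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    lfc = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if prior_df is None:
        d0, s02 = fit_variance_prior(s2, df)
    else:
        d0 = float(min(prior_df, _DF_CAP))
        _, s02 = fit_variance_prior(s2, df)
    if d0 > 0:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        s2_post = s2.copy()
    df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "s2": s2,
            "s2_post": s2_post,
        },
        index=expr.genes,
    )
    return DEResult(table, prior_df=d0, prior_var=s02, df_residual=float(df))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(
    res: DEResult,
    lfc_min: float = 1.0,
    p_adj_max: float = 0.05,
    direction: str = "both",
) -> list[str]:
    """Genes passing strict |log2FC| > lfc_min and BH p_adj < p_adj_max.

    ``direction`` selects up-regulated (A > B), down-regulated, or both.
    """
    if lfc_min <= 0 or p_adj_max <= 0:
        raise ValueError("thresholds must be positive")
    t = res.table
    if direction == "up":
        fc_ok = t["log2fc"] > lfc_min
    elif direction == "down":
        fc_ok = t["log2fc"] < -lfc_min
    elif direction == "both":
        fc_ok = t["log2fc"].abs() > lfc_min
    else:
        raise ValueError("direction must be 'up', 'down' or 'both'")
    keep = fc_ok & (t["p_adj"] < p_adj_max)
    return t.index[keep].tolist()
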