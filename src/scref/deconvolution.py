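"""Cell-fraction estimation from bulk expression by linear nu-SVR.

Solves m = f x B in linear expression units: the signature matrix B is
z-scored by its global mean and standard deviation, the mixture by its
own, a linear-kernel nu-SVR is fitted for each nu in a small grid, negative
coefficients are clipped, the vector renormalized to sum one, and the nu
whose reconstruction has the smallest root-mean-square error is kept.
Standardizing the mixture by its own statistics makes the estimate
invariant to rescaling of m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.svm import NuSVR

from .io_formats import ExpressionMatrix, Scale
from .reference_builder import ReferenceGEP

__all__ = [
    "DeconvConfig",
    "MixtureResult",
    "deconvolve",
    "deconvolve_cohort",
    "adjust_known_compartments",
]


@dataclass(frozen=True)
class DeconvConfig:
    """nu-SVR settings (the canonical CIBERSORT-style defaults)."""

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    c_penalty: float = 1.0
    standardize: bool = True
    nonneg_clip: bool = True

    def __post_init__(self) -> None:
        if not all(0 < nu <= 1 for nu in self.nu_grid):
            raise ValueError("nu values must lie in (0, 1]")
        if self.c_penalty <= 0:
            raise ValueError("c_penalty must be > 0")


@dataclass
class MixtureResult:
    """Estimated fractions for one bulk sample plus fit diagnostics."""

    fractions: pd.Series
    nu: float | None
    rmse: float
    pearson_fit: float
    sample_id: str = ""
    warning: str | None = None

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if np.isfinite(f).all():
            if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("fractions must be a probability vector")


def _gep_table(B) -> pd.DataFrame:
    return B.table if isinstance(B, ReferenceGEP) else B


def deconvolve(
    m: pd.Series,
    B: ReferenceGEP | pd.DataFrame,
    cfg: DeconvConfig | None = None,
    sample_id: str = "",
) -> MixtureResult:
    """Estimate cell-type fractions of one linear-scale bulk profile."""
    cfg = cfg or DeconvConfig()
    table = _gep_table(B)
    shared = table.index.intersection(m.index)
    if len(shared) < 2:
        raise ValueError("mixture and reference share fewer than 2 genes")
    X = table.loc[shared].to_numpy(dtype=float)
    y = m.loc[shared].to_numpy(dtype=float)
    types = list(table.columns)

    if cfg.standardize:
        x_sd = X.std()
        y_sd = y.std()
        if x_sd == 0 or y_sd == 0:
            return MixtureResult(
                pd.Series(np.full(len(types), 1.0 / len(types)), index=types),
                None, np.nan, np.nan, sample_id,
                warning="degenerate input (constant mixture or reference)",
            )
        X = (X - X.mean()) / x_sd
        y = (y - y.mean()) / y_sd

    best: tuple[float, float, np.ndarray, float] | None = None
    for nu in cfg.nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=cfg.c_penalty)
        model.fit(X, y)
        w = model.coef_.ravel().copy()
        if cfg.nonneg_clip:
            w[w < 0] = 0.0
        if w.sum() <= 0:
            continue
        f = w / w.sum()
        recon = X @ f
        rmse = float(np.sqrt(np.mean((y - recon) ** 2)))
        r = float(pearsonr(y, recon)[0]) if np.std(recon) > 0 else np.nan
        if best is None or rmse < best[0]:
            best = (rmse, nu, f, r)

    if best is None:
        warnings.warn("all nu-SVR coefficients non-positive; returning uniform fractions")
        return MixtureResult(
            pd.Series(np.full(len(types), 1.0 / len(types)), index=types),
            None, np.nan, np.nan, sample_id, warning="degenerate fit",
        )
    rmse, nu, f, r = best
    return MixtureResult(pd.Series(f, index=types), nu, rmse, r, sample_id)


def deconvolve_cohort(
    M: ExpressionMatrix,
    B: ReferenceGEP | pd.DataFrame,
    cfg: DeconvConfig | None = None,
) -> list[MixtureResult]:
    """Deconvolve each bulk sample independently, order preserved.

    Per-sample failures are returned as flagged results (NaN fractions),
    not raised.
    """
    if M.scale is not Scale.LINEAR_TPM:
        raise ValueError("bulk mixtures must be in linear units")
    types = list(_gep_table(B).columns)
    out: list[MixtureResult] = []
    for sample in M.samples:
        try:
            out.append(deconvolve(M.data[sample], B, cfg, sample_id=sample))
        except ValueError as exc:
            out.append(
                MixtureResult(
                    pd.Series(np.nan, index=types), None, np.nan, np.nan,
                    sample_id=sample, warning=str(exc),
                )
            )
    return out


def adjust_known_compartments(
    f_hat: pd.Series,
    known: dict[str, float],
) -> pd.Series:
    """Replace known compartment fractions and rescale the remainder.

    ``known`` maps cell types (e.g. malignant, stromal) to their true
    fractions; the remaining estimated fractions are rescaled
    proportionally to fill ``1 - sum(known)``.
    """
    for t, v in known.items():
        if t not in f_hat.index:
            raise ValueError(f"unknown compartment {t!r}")
        if not 0.0 <= v <= 1.0:
            raise ValueError("known fractions must lie in [0, 1]")
    known_total = float(sum(known.values()))
    if known_total > 1.0 + 1e-9:
        raise ValueError("known fractions sum above 1")
    out = f_hat.copy().astype(float)
    rest = out.index.difference(list(known))
    residual = 1.0 - known_total
    rest_sum = float(out[rest].sum())
    if rest_sum > 0:
        out[rest] = out[rest] / rest_sum * residual
    else:
        if residual > 1e-9:
            warnings.warn("no mass among remaining types; their fractions set to 0")
        out[rest] = 0.0
    for t, v in known.items():
        out[t] = v
    return out
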