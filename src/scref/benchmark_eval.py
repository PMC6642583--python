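"""In-silico benchmark: pseudo-bulk deconvolution scored against truth.

Each patient's cells are pooled into a linear-scale pseudo-bulk whose true
cell-type fractions are known by construction; reference GEPs built from
chosen gene panels are used to deconvolve the pseudo-bulks and accuracy is
summarized as Pearson correlations between true and estimated fractions,
per cell type and pooled over all (sample, type) pairs.  A leave-one-out
harness measures robustness to missing reference cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import DeconvConfig, deconvolve_cohort
from .io_formats import GeneSetCollection
from .reference_builder import ReferenceGEP, assemble_panels, build_gep
from .synthetic import T_SUBTYPES, SyntheticDataset, pool_pseudobulk

__all__ = [
    "BenchmarkReport",
    "pearson_r",
    "evaluate_panel",
    "evaluate_panels",
    "leave_one_out",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN for constant or too-short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class BenchmarkReport:
    """Accuracy summary for one panel on one pseudo-bulk cohort."""

    panel_name: str
    per_type_r: pd.Series
    overall_r: float
    tcell_aggregate_r: float
    estimated: pd.DataFrame  # samples x types
    truth: pd.DataFrame  # samples x types
    n_samples: int

    def delta_vs(self, other: "BenchmarkReport") -> pd.Series:
        """Per-type r difference (self minus other) over shared types."""
        shared = self.per_type_r.index.intersection(other.per_type_r.index)
        return self.per_type_r[shared] - other.per_type_r[shared]


def _score(estimated: pd.DataFrame, truth: pd.DataFrame, panel_name: str) -> BenchmarkReport:
    shared_types = [t for t in truth.columns if t in estimated.columns]
    est = estimated.loc[truth.index, shared_types]
    tru = truth[shared_types]
    if len(tru) < 3:
        raise ValueError("need at least 3 pseudo-bulk samples")
    per_type = pd.Series(
        {t: pearson_r(tru[t], est[t]) for t in shared_types}, name="pearson_r"
    )
    overall = pearson_r(tru.to_numpy().ravel(), est.to_numpy().ravel())
    t_subs = [t for t in T_SUBTYPES if t in shared_types]
    tcell_r = (
        pearson_r(tru[t_subs].sum(axis=1), est[t_subs].sum(axis=1)) if t_subs else float("nan")
    )
    return BenchmarkReport(panel_name, per_type, overall, tcell_r, est, tru, len(tru))


def _deconvolve_to_frame(bulk, gep, cfg) -> pd.DataFrame:
    results = deconvolve_cohort(bulk, gep, cfg)
    return pd.DataFrame(
        {res.sample_id: res.fractions for res in results}
    ).T.reindex(bulk.samples)


def evaluate_panel(
    ds: SyntheticDataset,
    panel: list[GeneSetCollection] | GeneSetCollection,
    cfg: DeconvConfig | None = None,
    labels: pd.Series | None = None,
    panel_name: str = "",
) -> BenchmarkReport:
    """Build a GEP from one panel (or panel ensemble), deconvolve the
    pooled pseudo-bulks and score the estimates against the true fractions.

    ``labels`` defaults to the generator's truth labels; passing the
    pipeline's own annotation isolates annotation error from
    deconvolution error.
    """
    colls = [panel] if isinstance(panel, GeneSetCollection) else list(panel)
    genes, provenance = assemble_panels(colls, ds.expression.genes)
    use_labels = labels if labels is not None else ds.truth_labels
    name = panel_name or "+".join(c.source_tag or "panel" for c in colls)
    gep = build_gep(
        ds.expression, use_labels, genes, panel_name=name, provenance=provenance
    )
    bulk, truth = pool_pseudobulk(ds)
    estimated = _deconvolve_to_frame(bulk, gep, cfg)
    return _score(estimated, truth, name)


def evaluate_panels(
    ds: SyntheticDataset,
    panels: dict[str, list[GeneSetCollection] | GeneSetCollection],
    cfg: DeconvConfig | None = None,
    labels: pd.Series | None = None,
) -> dict[str, BenchmarkReport]:
    """Score several panel ensembles on the same pseudo-bulk cohort."""
    return {
        name: evaluate_panel(ds, panel, cfg, labels, panel_name=name)
        for name, panel in panels.items()
    }


def leave_one_out(
    ds: SyntheticDataset,
    panel: list[GeneSetCollection] | GeneSetCollection,
    cfg: DeconvConfig | None = None,
    labels: pd.Series | None = None,
) -> tuple[BenchmarkReport, dict[str, BenchmarkReport]]:
    """Robustness to missing reference cell types.

    For each type the corresponding column is removed from the full GEP,
    the cohort re-deconvolved, and the remaining types re-scored; compare
    each report against the full-reference run with
    :meth:`BenchmarkReport.delta_vs`.
    """
    colls = [panel] if isinstance(panel, GeneSetCollection) else list(panel)
    genes, provenance = assemble_panels(colls, ds.expression.genes)
    use_labels = labels if labels is not None else ds.truth_labels
    gep = build_gep(ds.expression, use_labels, genes, provenance=provenance)
    if len(gep.cell_types) < 3:
        raise ValueError("leave-one-out needs at least 3 reference cell types")
    bulk, truth = pool_pseudobulk(ds)

    full = _score(_deconvolve_to_frame(bulk, gep, cfg), truth, "full")
    dropped: dict[str, BenchmarkReport] = {}
    for t in gep.cell_types:
        sub = gep.drop_type(t)
        est = _deconvolve_to_frame(bulk, sub, cfg)
        dropped[t] = _score(est, truth.drop(columns=[t]), f"minus_{t}")
    return full, dropped
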