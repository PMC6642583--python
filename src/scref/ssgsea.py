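"""Single-sample gene-set enrichment (ssGSEA) scoring.

For each sample independently, genes are ranked by expression and a
rank-weighted running sum is walked down the ranked list; the enrichment
score is the total (summed) deviation between the weighted in-set and the
uniform out-of-set cumulative distributions.  Scores are rank-based, hence
invariant to any strictly monotone transform of a sample's values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = ["SsgseaConfig", "ssgsea_scores", "cluster_mean_scores"]


@dataclass(frozen=True)
class SsgseaConfig:
    """ssGSEA scoring options.

    alpha
        Exponent weighting the rank of in-set genes (0 = unweighted
        Kuiper-style walk; 0.25 is the canonical ssGSEA choice).
    """

    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: SsgseaConfig | None = None,
) -> pd.DataFrame:
    """Per-sample enrichment scores, one column per gene set.

    Within each sample genes are walked in decreasing expression order
    (ties broken by gene symbol, which makes scores invariant to input row
    order).  Rank weights use average ranks on ties.  Sets with no gene in
    the matrix are dropped with a warning; a set covering every gene is an
    error because the out-of-set distribution is then undefined.
    """
    cfg = cfg or SsgseaConfig()
    n_genes = expr.shape[0]
    if n_genes < 2:
        raise ValueError("ssGSEA needs at least 2 genes")

    gene_index = pd.Index(expr.genes)
    # secondary tie-break key: lexicographic position of the gene symbol
    name_rank = np.empty(n_genes, dtype=int)
    name_rank[np.argsort(gene_index.to_numpy())] = np.arange(n_genes)

    memberships: dict[str, np.ndarray] = {}
    for name, genes in sets.sets.items():
        mask = gene_index.isin(genes)
        k = int(mask.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no gene in the matrix; dropped")
            continue
        if k == n_genes:
            raise ValueError(f"gene set {name!r} covers all genes; ES undefined")
        memberships[name] = mask
    if not memberships:
        raise ValueError("no gene set overlaps the expression matrix")

    values = expr.values
    out = np.empty((expr.shape[1], len(memberships)))
    for j in range(expr.shape[1]):
        v = values[:, j]
        order = np.lexsort((name_rank, -v))  # descending value, ties by symbol
        weight = rankdata(v, method="average") ** cfg.alpha  # (N - pos + 1) averaged
        for s, (name, mask) in enumerate(memberships.items()):
            in_set = mask[order]
            w = np.where(in_set, weight[order], 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (n_genes - in_set.sum())
            out[j, s] = float(np.sum(p_in - p_out))
    return pd.DataFrame(out, index=expr.samples, columns=list(memberships))


def cluster_mean_scores(scores: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Arithmetic mean of per-sample scores within each cluster."""
    missing = scores.index.difference(clusters.index)
    if len(missing):
        raise ValueError(f"samples without a cluster id: {list(missing[:5])}")
    return scores.groupby(clusters.reindex(scores.index)).mean()
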