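"""Marker selection, panel assembly and reference GEP construction.

Cell-type marker genes are selected from pairwise moderated-t comparisons:
a gene is a marker of a type when it is significantly higher in that type
than in at least ``min_other_types`` of the remaining types.  Reference
gene expression profiles (the B matrix) are per-type means of linearized
single-cell expression restricted to a gene panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_stats import moderated_ttest
from .io_formats import ExpressionMatrix, GeneSetCollection, Scale

__all__ = [
    "MarkerRuleConfig",
    "ReferenceGEP",
    "select_markers",
    "select_tumor_markers",
    "assemble_panels",
    "build_gep",
]


@dataclass(frozen=True)
class MarkerRuleConfig:
    """Thresholds of the marker rule (strict inequalities).

    A gene is a marker of type k when log2FC(k vs other) > ``lfc_min`` and
    BH-adjusted p < ``p_adj_max`` against at least ``min_other_types`` of
    the other types.
    """

    lfc_min: float = 3.0
    p_adj_max: float = 0.05
    min_other_types: int = 5

    def __post_init__(self) -> None:
        if self.lfc_min <= 0 or self.p_adj_max <= 0 or self.min_other_types < 1:
            raise ValueError("marker rule thresholds must be positive")


@dataclass
class ReferenceGEP:
    """The reference matrix B: panel genes x cell types, linear-scale means."""

    table: pd.DataFrame
    panel_name: str = ""
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate genes in reference GEP")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("reference GEP must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.table.columns)

    def drop_type(self, cell_type: str) -> "ReferenceGEP":
        """Leave-one-out copy without one cell-type column."""
        return ReferenceGEP(
            self.table.drop(columns=[cell_type]),
            panel_name=self.panel_name,
            provenance=self.provenance,
        )


def select_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    rule: MarkerRuleConfig | None = None,
) -> dict[str, list[str]]:
    """Select per-type marker genes from all pairwise comparisons.

    Each unordered pair of annotated types is compared once with a
    moderated t-test; a comparison "qualifies" for the higher type when the
    strict thresholds hold.  A gene qualifying for several types is
    assigned to the type with the most qualifying comparisons, ties broken
    by the larger median log2FC over its qualifying comparisons.  Types
    with fewer than two cells are excluded with a warning.
    """
    rule = rule or MarkerRuleConfig()
    labels = labels.reindex(expr.samples)
    counts = labels.value_counts()
    types = sorted(counts.index[counts >= 2])
    dropped = sorted(set(counts.index) - set(types))
    if dropped:
        warnings.warn(f"types with < 2 cells excluded from marker selection: {dropped}")
    if len(types) < 2:
        raise ValueError("marker selection needs at least 2 types with >= 2 cells")
    if rule.min_other_types > len(types) - 1:
        raise ValueError("min_other_types exceeds the number of other types")

    members = {t: labels.index[labels == t].tolist() for t in types}
    n_genes = expr.shape[0]
    qual_count = {t: np.zeros(n_genes, dtype=int) for t in types}
    qual_lfc: dict[str, list[np.ndarray]] = {t: [] for t in types}

    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            res = moderated_ttest(expr, members[a], members[b])
            lfc = res.table["log2fc"].to_numpy()
            sig = res.table["p_adj"].to_numpy() < rule.p_adj_max
            up_a = (lfc > rule.lfc_min) & sig
            up_b = (-lfc > rule.lfc_min) & sig
            qual_count[a] += up_a
            qual_count[b] += up_b
            qual_lfc[a].append(np.where(up_a, lfc, np.nan))
            qual_lfc[b].append(np.where(up_b, -lfc, np.nan))

    gene_arr = expr.genes.to_numpy()
    candidates: dict[int, list[str]] = {}
    for t in types:
        hit = qual_count[t] >= rule.min_other_types
        for gi in np.nonzero(hit)[0]:
            candidates.setdefault(int(gi), []).append(t)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        med = {t: np.nanmedian(np.vstack(qual_lfc[t]), axis=0) for t in types}

    markers: dict[str, list[str]] = {t: [] for t in types}
    for gi, ts in candidates.items():
        if len(ts) == 1:
            winner = ts[0]
        else:
            winner = max(ts, key=lambda t: (qual_count[t][gi], med[t][gi]))
        markers[winner].append(gene_arr[gi])
    return {t: sorted(g) for t, g in markers.items() if g}


def select_tumor_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    tumor_label: str = "Malignant",
    rule: MarkerRuleConfig | None = None,
) -> list[str]:
    """Tumor-vs-non-tumor markers (the M1-style panel): a two-group run of
    the marker rule with ``min_other_types = 1``."""
    rule = rule or MarkerRuleConfig()
    two_group = labels.map(lambda t: tumor_label if t == tumor_label else "NonTumor")
    res = select_markers(
        expr,
        two_group,
        MarkerRuleConfig(rule.lfc_min, rule.p_adj_max, min_other_types=1),
    )
    return res.get(tumor_label, [])


def assemble_panels(
    panels: list[GeneSetCollection],
    available_genes,
) -> tuple[list[str], dict[str, list[str]]]:
    """Union of panel gene lists, intersected with the expression genes.

    Returns the merged gene list (first-occurrence order) and a per-gene
    provenance map (which source panels contributed it).  Genes absent from
    the matrix are dropped with a logged count; an empty result is an error.
    """
    if not panels:
        raise ValueError("no panels given")
    available = set(available_genes)
    merged: dict[str, list[str]] = {}
    n_missing = 0
    for coll in panels:
        tag = coll.source_tag or "panel"
        for g in coll.all_genes():
            if g not in available:
                n_missing += 1
                continue
            tags = merged.setdefault(g, [])
            if tag not in tags:
                tags.append(tag)
    if n_missing:
        warnings.warn(f"{n_missing} panel gene reference(s) absent from the matrix")
    if not merged:
        raise ValueError("panel union has no gene in common with the matrix")
    return list(merged), merged


def build_gep(
    expr: ExpressionMatrix,
    labels: pd.Series,
    gene_panel,
    exclude_unassigned: bool = True,
    log_space: bool = False,
    panel_name: str = "",
    provenance: dict[str, list[str]] | None = None,
) -> ReferenceGEP:
    """Average annotated single cells per type over a gene panel.

    Expression is linearized (``2**y - 1``) before averaging unless
    ``log_space`` is set (sensitivity analysis only).  Types with no cell
    are omitted with a warning; cells labeled ``unassigned`` are excluded
    by default.
    """
    labels = labels.reindex(expr.samples)
    keep = labels.notna()
    if exclude_unassigned:
        keep &= labels != "unassigned"
    labels = labels[keep]
    if labels.empty:
        raise ValueError("no annotated cells to average")
    panel = [g for g in gene_panel if g in set(expr.genes)]
    if not panel:
        raise ValueError("gene panel has no overlap with the matrix")
    data = expr.subset_genes(panel).subset_samples(labels.index)
    if not log_space:
        data = data.to_linear()
    means = data.data.T.groupby(labels).mean().T
    empty = [t for t in pd.unique(labels) if t not in means.columns]
    if empty:  # pragma: no cover - defensive; groupby covers observed labels
        warnings.warn(f"types without cells omitted from GEP: {empty}")
    return ReferenceGEP(
        means,
        panel_name=panel_name,
        provenance=provenance or {},
    )
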