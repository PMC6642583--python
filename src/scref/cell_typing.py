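"""Multi-stage adaptive cell-type identification.

Stage 1 separates malignant from non-malignant cells (t-SNE embedding +
DBSCAN, clusters labeled by their mean tumor-signature enrichment).
Stage 2 assigns the remaining cells to the major immune and stromal types.
Stage 3 resolves the lumped T-cell population into four subtypes with
SC3-style consensus clustering and a differential-expression call on
exhaustion / Treg marker programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .de_stats import moderated_ttest
from .io_formats import ExpressionMatrix, GeneSetCollection
from .ssgsea import SsgseaConfig, cluster_mean_scores, ssgsea_scores
from .synthetic import MAJOR_NON_T_TYPES, T_SUBTYPES

__all__ = [
    "ClusterParams",
    "StageConfig",
    "embed_and_cluster",
    "label_clusters",
    "split_malignant",
    "split_major_types",
    "consensus_cluster_tcells",
    "assign_t_subtypes",
    "annotate_cells",
    "major_type_sets",
    "DEFAULT_EXHAUSTION_MARKERS",
    "DEFAULT_TREG_MARKERS",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

#: Built-in exhaustion program used to orient the CD8 split (over-ridable).
DEFAULT_EXHAUSTION_MARKERS = ("PDCD1", "TIGIT", "CTLA4", "HAVCR2")
#: Built-in regulatory program used to orient the CD4 split (over-ridable).
DEFAULT_TREG_MARKERS = ("FOXP3", "TIGIT", "CTLA4")


@dataclass(frozen=True)
class ClusterParams:
    """t-SNE + DBSCAN parameters for one embedding/clustering stage."""

    perplexity: float
    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.min_pts < 1 or self.perplexity <= 0:
            raise ValueError("invalid clustering parameters")


@dataclass(frozen=True)
class StageConfig:
    """Parameters of the three identification stages."""

    stage1: ClusterParams = ClusterParams(perplexity=50, eps=5.0, min_pts=5)
    stage2: ClusterParams = ClusterParams(perplexity=30, eps=6.0, min_pts=15)
    k_tcell: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_tcell < 2:
            raise ValueError("k_tcell must be >= 2")


def embed_and_cluster(
    expr: ExpressionMatrix,
    perplexity: float,
    eps: float,
    min_pts: int,
    seed: int = 0,
    pca_dims: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """Seeded 2-D t-SNE embedding followed by DBSCAN density clustering.

    Cells are first reduced to ``pca_dims`` principal components (the
    convention of Rtsne-style pipelines), embedded in 2-D, and clustered
    with DBSCAN(eps, min_pts); noise cells receive cluster id -1.  Returns
    per-cell cluster ids and the embedding coordinates.
    """
    x = expr.data.T.to_numpy()
    n = x.shape[0]
    if n < 5:
        raise ValueError("too few cells to embed")
    perp = perplexity
    if perp >= (n - 1) / 3.0:
        perp = max(2.0, (n - 1) / 3.0 - 1.0)
        warnings.warn(f"perplexity {perplexity} too large for {n} cells; using {perp:.1f}")
    d = min(pca_dims, n - 1, x.shape[1])
    if d < x.shape[1]:
        x = PCA(n_components=d, random_state=seed).fit_transform(x)
    emb = TSNE(
        n_components=2,
        perplexity=perp,
        random_state=seed,
        init="pca",
    ).fit_transform(x)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(emb)
    if (labels == -1).all():
        raise RuntimeError(
            "DBSCAN marked every cell as noise; adjust eps/min_pts (clusters "
            "should maximize the degree of differentiation)"
        )
    clusters = pd.Series(labels, index=expr.samples, name="cluster")
    coords = pd.DataFrame(emb, index=expr.samples, columns=["tsne1", "tsne2"])
    return clusters, coords


def label_clusters(
    clusters: pd.Series,
    scores: pd.DataFrame,
    candidate_sets: list[str] | None = None,
) -> dict[int, str]:
    """Label each non-noise cluster by the argmax of its mean enrichment.

    Ties are broken toward the lexicographically smallest set name with a
    warning.  Noise cells (cluster -1) are not labeled.
    """
    candidates = list(candidate_sets) if candidate_sets is not None else list(scores.columns)
    if not candidates:
        raise ValueError("candidate set list is empty")
    missing = set(candidates) - set(scores.columns)
    if missing:
        raise ValueError(f"candidate sets missing from score matrix: {sorted(missing)}")
    means = cluster_mean_scores(scores[candidates], clusters)
    out: dict[int, str] = {}
    for cl, row in means.iterrows():
        if cl == -1:
            continue
        best = row.max()
        winners = sorted(row.index[row == best])
        if len(winners) > 1:
            warnings.warn(f"cluster {cl}: tied enrichment for {winners}; using {winners[0]}")
        out[int(cl)] = winners[0]
    return out


def split_malignant(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: StageConfig | None = None,
    tumor_set: str = "Malignant",
    scores: pd.DataFrame | None = None,
    patient_ids: pd.Series | None = None,
) -> tuple[list[str], list[str], dict]:
    """Stage 1: separate malignant from non-malignant cells.

    A cluster is called malignant iff the tumor signature is the argmax of
    its mean enrichment over all candidate signatures.  Diagnostics include
    the cluster map, per-cluster labels, noise cells, and (when patient ids
    are supplied) each cluster's majority-patient share — malignant clusters
    are expected to be patient-dominated.
    """
    cfg = cfg or StageConfig()
    if tumor_set not in sets:
        raise ValueError(f"tumor signature {tumor_set!r} not in gene sets")
    if scores is None:
        scores = ssgsea_scores(expr, sets, SsgseaConfig())
    clusters, coords = embed_and_cluster(
        expr, cfg.stage1.perplexity, cfg.stage1.eps, cfg.stage1.min_pts, seed=cfg.seed
    )
    labels = label_clusters(clusters, scores)
    malignant_clusters = {cl for cl, lab in labels.items() if lab == tumor_set}
    if not malignant_clusters:
        warnings.warn("no cluster labeled malignant; returning empty malignant set")
    is_noise = clusters == -1
    is_mal = clusters.isin(malignant_clusters)
    malignant = clusters.index[is_mal].tolist()
    non_malignant = clusters.index[~is_mal & ~is_noise].tolist()
    diagnostics: dict = {
        "clusters": clusters,
        "cluster_labels": labels,
        "embedding": coords,
        "noise_ids": clusters.index[is_noise].tolist(),
    }
    if patient_ids is not None:
        comp = {}
        for cl in sorted(labels):
            cells = clusters.index[clusters == cl]
            share = patient_ids.reindex(cells).value_counts(normalize=True)
            comp[cl] = float(share.iloc[0]) if len(share) else np.nan
        diagnostics["majority_patient_share"] = comp
    return malignant, non_malignant, diagnostics


def major_type_sets(sets: GeneSetCollection) -> GeneSetCollection:
    """Candidate signatures for stage 2: six non-T majors plus a lumped T set.

    The ``Tcell`` signature is the union of the four T-subtype signatures
    when they are present; an existing ``Tcell`` set is used as-is.
    """
    out: dict[str, list[str]] = {}
    for name in MAJOR_NON_T_TYPES:
        if name in sets:
            out[name] = list(sets[name])
    if "Tcell" in sets:
        out["Tcell"] = list(sets["Tcell"])
    else:
        union: dict[str, None] = {}
        for name in T_SUBTYPES:
            if name in sets:
                for g in sets[name]:
                    union.setdefault(g, None)
        if union:
            out["Tcell"] = list(union)
    if not out:
        raise ValueError("no major-type signatures available")
    return GeneSetCollection(out, sets.source_tag)


def split_major_types(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: StageConfig | None = None,
    scores: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Stage 2: assign non-malignant cells to major immune/stromal types.

    Returns per-cell labels over the seven major types (noise cells get
    ``unassigned``) and the underlying cluster ids.
    """
    cfg = cfg or StageConfig()
    majors = major_type_sets(sets)
    if scores is None:
        scores = ssgsea_scores(expr, majors, SsgseaConfig())
    clusters, _ = embed_and_cluster(
        expr, cfg.stage2.perplexity, cfg.stage2.eps, cfg.stage2.min_pts, seed=cfg.seed
    )
    candidates = [n for n in majors.names if n in scores.columns]
    cl_labels = label_clusters(clusters, scores, candidates)
    labels = clusters.map(lambda c: cl_labels.get(int(c), UNASSIGNED) if c != -1 else UNASSIGNED)
    labels.name = "major_type"
    return labels, clusters


def consensus_cluster_tcells(
    expr: ExpressionMatrix,
    k: int = 4,
    seed: int = 0,
    d_fracs: tuple[float, ...] = (0.04, 0.05, 0.06, 0.07),
) -> tuple[pd.Series, pd.DataFrame]:
    """SC3-style consensus clustering of the T-cell population.

    Euclidean, Pearson and Spearman distance matrices are each projected on
    their leading principal components for a small range of dimensions
    (4-7% of the number of cells), k-means is run on every projection, and
    the runs are combined into a co-clustering frequency matrix which is
    hierarchically clustered (average linkage) and cut at ``k``.
    """
    x = expr.data.T.to_numpy()
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    dists = [squareform(pdist(x, metric="euclidean"))]
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(x)
        ranks = np.apply_along_axis(rankdata, 1, x)
        scor = np.corrcoef(ranks)
    dists.append(1.0 - np.nan_to_num(cor, nan=0.0))
    dists.append(1.0 - np.nan_to_num(scor, nan=0.0))

    d_values = sorted({min(max(2, int(round(f * n))), n - 1) for f in d_fracs})
    runs: list[np.ndarray] = []
    for di, dist in enumerate(dists):
        pca = PCA(n_components=max(d_values), random_state=seed)
        comps = pca.fit_transform(dist)
        for d in d_values:
            km = KMeans(n_clusters=k, random_state=seed + di, n_init=10)
            runs.append(km.fit_predict(comps[:, :d]))

    consensus = np.zeros((n, n))
    for lab in runs:
        consensus += (lab[:, None] == lab[None, :])
    consensus /= len(runs)

    agg = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
    labels = agg.fit_predict(1.0 - consensus)
    return (
        pd.Series(labels, index=expr.samples, name="t_cluster"),
        pd.DataFrame(consensus, index=expr.samples, columns=expr.samples),
    )


def _majority_up(de_table: pd.DataFrame, marker_genes, lfc_min: float, p_max: float) -> int:
    """Net count of marker genes significantly up (+) vs down (-) in group A."""
    present = [g for g in marker_genes if g in de_table.index]
    if not present:
        return 0
    sub = de_table.loc[present]
    up = int(((sub["log2fc"] > lfc_min) & (sub["p_adj"] < p_max)).sum())
    down = int(((sub["log2fc"] < -lfc_min) & (sub["p_adj"] < p_max)).sum())
    return up - down


def assign_t_subtypes(
    expr: ExpressionMatrix,
    t_clusters: pd.Series,
    sets: GeneSetCollection,
    exhaustion_genes=DEFAULT_EXHAUSTION_MARKERS,
    treg_genes=DEFAULT_TREG_MARKERS,
    lfc_min: float = 1.0,
    p_adj_max: float = 0.05,
    scores: pd.DataFrame | None = None,
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Stage 3: name the four T-cell consensus clusters.

    Clusters are first split into a CD4 and a CD8 side by the argmax of the
    mean enrichment of the pooled CD4 (Tconv+Treg) vs pooled CD8
    (Tconv+exhausted) signatures.  Within each side a moderated t-test
    orients the pair: the cluster whose exhaustion (resp. Treg) program is
    predominantly up-regulated is labeled exhausted (resp. Treg), the other
    conventional.  If the side split is not 2-vs-2, labeling falls back to
    a per-cluster argmax over the four subtype signatures with a warning.
    Returns per-cell subtype labels and the two DE tables (the T1 panel).
    """
    for name in T_SUBTYPES:
        if name not in sets:
            raise ValueError(f"subtype signature {name!r} missing from gene sets")
    side_sets = GeneSetCollection(
        {
            "CD4side": sorted(set(sets["CD4Tconv"]) | set(sets["Treg"])),
            "CD8side": sorted(set(sets["CD8Tconv"]) | set(sets["CD8Texhausted"])),
        }
    )
    side_scores = ssgsea_scores(expr, side_sets, SsgseaConfig())
    side_means = cluster_mean_scores(side_scores, t_clusters)
    sides = side_means.idxmax(axis=1)
    cd4 = sorted(int(c) for c in sides.index[sides == "CD4side"])
    cd8 = sorted(int(c) for c in sides.index[sides == "CD8side"])

    de_tables: dict[str, pd.DataFrame] = {}
    cluster_label: dict[int, str] = {}

    if len(cd4) == 2 and len(cd8) == 2:
        for side, pair, marker_set, hi_label, lo_label, key in (
            ("CD8", cd8, exhaustion_genes, "CD8Texhausted", "CD8Tconv", "CD8"),
            ("CD4", cd4, treg_genes, "Treg", "CD4Tconv", "CD4"),
        ):
            a = t_clusters.index[t_clusters == pair[0]].tolist()
            b = t_clusters.index[t_clusters == pair[1]].tolist()
            res = moderated_ttest(expr, a, b)
            de_tables[key] = res.table
            net = _majority_up(res.table, marker_set, lfc_min, p_adj_max)
            if net > 0:
                cluster_label[pair[0]], cluster_label[pair[1]] = hi_label, lo_label
            elif net < 0:
                cluster_label[pair[0]], cluster_label[pair[1]] = lo_label, hi_label
            else:
                warnings.warn(
                    f"{side} pair: marker program gave no direction; "
                    "falling back to signature argmax"
                )
                sub_scores = scores if scores is not None else ssgsea_scores(
                    expr, sets.subset(T_SUBTYPES), SsgseaConfig()
                )
                sub_means = cluster_mean_scores(sub_scores, t_clusters)
                for cl in pair:
                    cands = (hi_label, lo_label)
                    cluster_label[cl] = sub_means.loc[cl, list(cands)].idxmax()
    else:
        warnings.warn(
            f"CD4/CD8 split is {len(cd4)}-vs-{len(cd8)}, not 2-vs-2; "
            "falling back to per-cluster subtype argmax"
        )
        sub_scores = scores if scores is not None else ssgsea_scores(
            expr, sets.subset(T_SUBTYPES), SsgseaConfig()
        )
        sub_means = cluster_mean_scores(sub_scores, t_clusters)
        for cl in sub_means.index:
            cluster_label[int(cl)] = sub_means.loc[cl].idxmax()

    labels = t_clusters.map(lambda c: cluster_label[int(c)])
    labels.name = "t_subtype"
    return labels, de_tables


def annotate_cells(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: StageConfig | None = None,
    patient_ids: pd.Series | None = None,
    exhaustion_genes=DEFAULT_EXHAUSTION_MARKERS,
    treg_genes=DEFAULT_TREG_MARKERS,
) -> pd.DataFrame:
    """Run the full three-stage identification and return per-cell annotation.

    Columns: patient_id (when given), stage1_cluster, stage2_cluster,
    stage3_cluster, final_label, label_score (enrichment margin of the
    assigned signature over the runner-up; NaN for unassigned cells).
    """
    cfg = cfg or StageConfig()
    scores = ssgsea_scores(expr, sets, SsgseaConfig())

    malignant, non_malignant, diag = split_malignant(
        expr, sets, cfg, scores=scores, patient_ids=patient_ids
    )
    ann = pd.DataFrame(index=expr.samples)
    if patient_ids is not None:
        ann["patient_id"] = patient_ids.reindex(expr.samples)
    ann["stage1_cluster"] = diag["clusters"]
    ann["stage2_cluster"] = pd.NA
    ann["stage3_cluster"] = pd.NA
    ann["final_label"] = UNASSIGNED
    ann.loc[malignant, "final_label"] = "Malignant"

    t_cells: list[str] = []
    if non_malignant:
        sub = expr.subset_samples(non_malignant)
        major_labels, stage2_clusters = split_major_types(sub, sets, cfg)
        ann.loc[non_malignant, "stage2_cluster"] = stage2_clusters
        for name in MAJOR_NON_T_TYPES:
            ids = major_labels.index[major_labels == name]
            ann.loc[ids, "final_label"] = name
        t_cells = major_labels.index[major_labels == "Tcell"].tolist()

    if len(t_cells) >= cfg.k_tcell:
        t_expr = expr.subset_samples(t_cells)
        t_clusters, _ = consensus_cluster_tcells(t_expr, k=cfg.k_tcell, seed=cfg.seed)
        subtype_labels, _ = assign_t_subtypes(
            t_expr, t_clusters, sets, exhaustion_genes, treg_genes
        )
        ann.loc[t_cells, "stage3_cluster"] = t_clusters
        ann.loc[t_cells, "final_label"] = subtype_labels
    elif t_cells:
        warnings.warn("too few T cells for consensus clustering; left unassigned")

    # enrichment margin of the assigned label, where a matching set exists
    margin = np.full(len(ann), np.nan)
    score_cols = set(scores.columns)
    for i, (cell, lab) in enumerate(ann["final_label"].items()):
        if lab in score_cols:
            row = scores.loc[cell]
            margin[i] = row[lab] - row.drop(lab).max()
    ann["label_score"] = margin
    return ann
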