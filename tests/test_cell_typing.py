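"""Embedding/density clustering, cluster labeling, and the staged splits."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scref import (
    ExpressionMatrix,
    GeneSetCollection,
    SimulationConfig,
    StageConfig,
    simulate_dataset,
)
from scref.cell_typing import (
    assign_t_subtypes,
    consensus_cluster_tcells,
    embed_and_cluster,
    label_clusters,
    major_type_sets,
    split_major_types,
    split_malignant,
)
from scref.ssgsea import ssgsea_scores


def _blob_matrix(rng, n_cells_per_blob, offsets, n_genes=120, noise=0.5):
    """Cells in blobs separated by planted offsets on disjoint gene blocks."""
    blocks = []
    labels = []
    for b, (start, width, height) in enumerate(offsets):
        y = rng.normal(2.0, noise, (n_genes, n_cells_per_blob)).clip(min=0)
        y[start : start + width] += height
        blocks.append(y)
        labels += [b] * n_cells_per_blob
    values = np.hstack(blocks)
    cells = [f"c{i}" for i in range(values.shape[1])]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=[f"G{i}" for i in range(n_genes)], columns=cells)
    )
    return expr, np.array(labels)


class TestEmbedAndCluster:
    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        expr, truth = _blob_matrix(
            rng, 200, [(0, 50, 10.0), (50, 50, 10.0)], n_genes=120
        )
        clusters, _ = embed_and_cluster(expr, perplexity=40, eps=5, min_pts=5, seed=0)
        non_noise = clusters[clusters != -1]
        assert non_noise.nunique() == 2
        assert adjusted_rand_score(truth, clusters) == pytest.approx(1.0)

    def test_duplicated_cells_co_cluster(self):
        """Identical cells land on identical embedding coordinates, so each
        duplicate pair falls in one density cluster (eps matched to the
        wider spread a small duplicated instance produces)."""
        rng = np.random.default_rng(1)
        expr, _ = _blob_matrix(rng, 60, [(0, 40, 8.0), (40, 40, 8.0)], n_genes=100)
        dup = ExpressionMatrix(
            pd.concat(
                [expr.data, expr.data.add_suffix("_dup", axis=1)], axis=1
            )
        )
        clusters, emb = embed_and_cluster(dup, perplexity=30, eps=70, min_pts=5, seed=2)
        pair_dist = np.linalg.norm(
            emb.loc[expr.samples].to_numpy()
            - emb.loc[[c + "_dup" for c in expr.samples]].to_numpy(),
            axis=1,
        )
        assert pair_dist.max() < 1e-3
        for cell in expr.samples:
            a, b = clusters[cell], clusters[cell + "_dup"]
            if a != -1 and b != -1:
                assert a == b

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        expr, _ = _blob_matrix(rng, 75, [(0, 40, 8.0), (40, 40, 8.0)], n_genes=100)
        c1, e1 = embed_and_cluster(expr, perplexity=30, eps=5, min_pts=5, seed=7)
        c2, e2 = embed_and_cluster(expr, perplexity=30, eps=5, min_pts=5, seed=7)
        assert c1.equals(c2)
        assert np.allclose(e1.to_numpy(), e2.to_numpy())


class TestLabelClusters:
    def test_unanimous_cluster_gets_its_signature(self):
        scores = pd.DataFrame(
            {"Tcell": [5.0, 6.0, 1.0], "Bcell": [1.0, 2.0, 7.0]},
            index=["c0", "c1", "c2"],
        )
        clusters = pd.Series([0, 0, 1], index=scores.index)
        labels = label_clusters(clusters, scores)
        assert labels == {0: "Tcell", 1: "Bcell"}

    def test_random_scores_match_argmax_oracle(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            rng.normal(size=(40, 5)),
            index=[f"c{i}" for i in range(40)],
            columns=list("ABCDE"),
        )
        clusters = pd.Series(rng.integers(-1, 4, 40), index=scores.index)
        labels = label_clusters(clusters, scores)
        for cl in set(clusters) - {-1}:
            members = clusters.index[clusters == cl]
            assert labels[cl] == scores.loc[members].mean().idxmax()

    def test_removing_a_candidate_promotes_runner_up(self):
        """Argmax contract: without its winning signature a cluster takes
        the runner-up label."""
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(
            rng.normal(size=(30, 4)), index=[f"c{i}" for i in range(30)],
            columns=["Mast", "Bcell", "Tcell", "Dendritic"],
        )
        scores["Mast"] += 3.0  # every cluster prefers Mast
        clusters = pd.Series(rng.integers(0, 3, 30), index=scores.index)
        full = label_clusters(clusters, scores)
        reduced = label_clusters(clusters, scores, ["Bcell", "Tcell", "Dendritic"])
        means = scores.groupby(clusters).mean()
        for cl, label in full.items():
            assert label == "Mast"
            assert reduced[cl] == means.loc[cl].drop("Mast").idxmax()

    def test_empty_candidates_rejected(self):
        scores = pd.DataFrame({"A": [1.0]}, index=["c0"])
        with pytest.raises(ValueError, match="empty"):
            label_clusters(pd.Series([0], index=["c0"]), scores, [])


@pytest.fixture(scope="module")
def mid_ds():
    """A mid-size cohort for the stage-level splits (fast but realistic)."""
    return simulate_dataset(
        SimulationConfig(
            n_patients=6, cells_per_patient=150, n_genes=600,
            n_markers_per_type=10, seed=11,
        )
    )


class TestSplitMalignant:
    def test_recall_and_precision_against_truth(self, mid_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            malignant, non_malignant, diag = split_malignant(
                mid_ds.expression, mid_ds.signature_sets(), StageConfig(seed=0),
                patient_ids=mid_ds.patient_ids,
            )
        truth = set(mid_ds.truth_labels.index[mid_ds.truth_labels == "Malignant"])
        got = set(malignant)
        recall = len(got & truth) / len(truth)
        precision = len(got & truth) / max(len(got), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_malignant_clusters_are_patient_dominated(self, mid_ds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, diag = split_malignant(
                mid_ds.expression, mid_ds.signature_sets(), StageConfig(seed=0),
                patient_ids=mid_ds.patient_ids,
            )
        shares = diag["majority_patient_share"]
        labels = diag["cluster_labels"]
        mal = [shares[cl] for cl, lab in labels.items() if lab == "Malignant"]
        other = [shares[cl] for cl, lab in labels.items() if lab != "Malignant"]
        assert mal and other
        assert np.mean(mal) >= np.mean(other)

    def test_no_malignant_cells_yields_empty_set_with_warning(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_patients=4, cells_per_patient=100, n_genes=500,
                n_markers_per_type=8, malignant_fraction_range=(0.0, 0.0), seed=6,
            )
        )
        with pytest.warns(UserWarning, match="no cluster labeled malignant"):
            malignant, _, _ = split_malignant(
                ds.expression, ds.signature_sets(), StageConfig(seed=0)
            )
        assert malignant == []


class TestSplitMajorTypes:
    def test_per_type_f1_on_non_malignant_cells(self, default_ds):
        # the full-size cohort: every major type is populous enough for the
        # stage-2 density clustering's min_pts of 15
        truth = default_ds.truth_labels
        non_mal = truth.index[truth != "Malignant"]
        sub = default_ds.expression.subset_samples(non_mal)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels, _ = split_major_types(sub, default_ds.signature_sets(), StageConfig(seed=0))
        major_truth = truth[non_mal].map(
            lambda t: "Tcell" if t in ("CD4Tconv", "Treg", "CD8Tconv", "CD8Texhausted") else t
        )
        for cell_type in major_truth.unique():
            tp = ((labels == cell_type) & (major_truth == cell_type)).sum()
            fp = ((labels == cell_type) & (major_truth != cell_type)).sum()
            fn = ((labels != cell_type) & (major_truth == cell_type)).sum()
            f1 = 2 * tp / max(2 * tp + fp + fn, 1)
            assert f1 >= 0.9, cell_type

    def test_homogeneous_input_gets_one_dominant_label(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_patients=2, cells_per_patient=120, n_genes=500, n_markers_per_type=8,
                malignant_fraction_range=(0.0, 0.0), seed=8,
                cell_types=("Malignant", "Fibroblast"),
            )
        )
        sets = GeneSetCollection(
            {
                "Fibroblast": ds.planted_markers["Fibroblast"],
                "Bcell": ["ABSENT1", "ABSENT2"],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels, _ = split_major_types(
                ds.expression, sets, StageConfig(seed=0)
            )
        assert (labels == "Fibroblast").mean() >= 0.95


@pytest.fixture(scope="module")
def t_blobs():
    rng = np.random.default_rng(5)
    return _blob_matrix(
        rng, 60,
        [(0, 15, 4.0), (15, 15, 4.0), (30, 15, 4.0), (45, 15, 4.0)],
        n_genes=200, noise=1.0,
    )


class TestConsensusTcells:
    def test_four_planted_subtype_blobs_recovered(self, t_blobs):
        expr, truth = t_blobs
        labels, consensus = consensus_cluster_tcells(expr, k=4, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_consensus_matrix_is_a_frequency_matrix(self, t_blobs):
        expr, _ = t_blobs
        _, consensus = consensus_cluster_tcells(expr, k=4, seed=0)
        c = consensus.to_numpy()
        assert ((0.0 <= c) & (c <= 1.0)).all()
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)

    def test_duplicated_cells_have_consensus_one(self):
        rng = np.random.default_rng(6)
        expr, _ = _blob_matrix(rng, 30, [(0, 20, 4.0), (20, 20, 4.0)], n_genes=100)
        dup = ExpressionMatrix(
            pd.concat([expr.data, expr.data.add_suffix("_dup", axis=1)], axis=1)
        )
        _, consensus = consensus_cluster_tcells(dup, k=2, seed=0)
        for cell in expr.samples:
            assert consensus.loc[cell, cell + "_dup"] == pytest.approx(1.0)

    def test_fewer_cells_than_k_rejected(self):
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.ones((10, 3)), index=[f"G{i}" for i in range(10)],
                columns=["a", "b", "c"],
            )
        )
        with pytest.raises(ValueError, match="at least k"):
            consensus_cluster_tcells(expr, k=4)


@pytest.fixture(scope="module")
def t_cells():
    """Synthetic T cells: the generator restricted to the 4 subtypes."""
    ds = simulate_dataset(
        SimulationConfig(
            n_patients=4, cells_per_patient=120, n_genes=500, n_markers_per_type=10,
            malignant_fraction_range=(0.0, 0.0), seed=13,
            cell_types=("Malignant", "CD4Tconv", "Treg", "CD8Tconv", "CD8Texhausted"),
        )
    )
    t_ids = ds.truth_labels.index[ds.truth_labels != "Malignant"]
    expr = ds.expression.subset_samples(t_ids)
    truth = ds.truth_labels[t_ids]
    clusters = pd.Series(
        pd.factorize(truth)[0], index=t_ids
    )  # perfect clustering; this test isolates the naming step
    sets = ds.signature_sets().subset(
        ["CD4Tconv", "Treg", "CD8Tconv", "CD8Texhausted"]
    )
    return ds, expr, truth, clusters, sets


class TestAssignTSubtypes:

    def test_planted_exhaustion_program_names_the_exhausted_cluster(self, t_cells):
        ds, expr, truth, clusters, sets = t_cells
        labels, de_tables = assign_t_subtypes(
            expr, clusters, sets,
            exhaustion_genes=ds.planted_markers["CD8Texhausted"],
            treg_genes=ds.planted_markers["Treg"],
        )
        assert (labels == truth).mean() == pytest.approx(1.0)
        assert set(de_tables) == {"CD4", "CD8"}

    def test_labels_follow_genes_not_cluster_order(self, t_cells):
        ds, expr, truth, clusters, sets = t_cells
        relabel = {0: 3, 1: 2, 2: 1, 3: 0}
        swapped = clusters.map(relabel)
        labels, _ = assign_t_subtypes(
            expr, swapped, sets,
            exhaustion_genes=ds.planted_markers["CD8Texhausted"],
            treg_genes=ds.planted_markers["Treg"],
        )
        assert (labels == truth).mean() == pytest.approx(1.0)

    def test_non_2v2_split_falls_back_to_argmax(self, t_cells):
        ds, expr, truth, clusters, sets = t_cells
        # merge the two CD8 clusters and split one CD4 cluster arbitrarily
        cd8_ids = truth.index[truth.isin(["CD8Tconv", "CD8Texhausted"])]
        broken = clusters.copy()
        broken[cd8_ids] = 9
        cd4_ids = truth.index[truth == "CD4Tconv"]
        half = cd4_ids[: len(cd4_ids) // 2]
        broken[half] = 8
        with pytest.warns(UserWarning, match="not 2-vs-2"):
            labels, _ = assign_t_subtypes(expr, broken, sets)
        assert set(labels.unique()) <= {
            "CD4Tconv", "Treg", "CD8Tconv", "CD8Texhausted"
        }


class TestMajorTypeSets:
    def test_tcell_signature_is_union_of_subtypes(self):
        sets = GeneSetCollection(
            {
                "Fibroblast": ["F1"],
                "CD4Tconv": ["A", "B"],
                "Treg": ["B", "C"],
                "CD8Tconv": ["D"],
                "CD8Texhausted": ["E"],
            }
        )
        majors = major_type_sets(sets)
        assert set(majors["Tcell"]) == {"A", "B", "C", "D", "E"}
        assert majors["Fibroblast"] == ["F1"]
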