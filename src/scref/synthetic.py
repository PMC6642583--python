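"""Synthetic single-cell tumor datasets with known cell-type composition.

The generator emulates the statistical structure the deconvolution pipeline
relies on in a Smart-seq2-style head-and-neck tumor cohort: a shared
per-gene baseline, planted cell-type marker programs, patient-specific
expression shifts confined to malignant cells (so malignant cells cluster
by patient while immune and stromal cells cluster by type), tumor purity
varying uniformly across patients, Gaussian log-scale noise and
dropout-style zero inflation.  Ground-truth labels, per-patient fractions
and the planted marker map travel with the expression matrix so every
downstream stage can be scored against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    Scale,
    write_annotation_csv,
    write_expression_tsv,
    write_gmt,
)

__all__ = [
    "CELL_TYPES",
    "T_SUBTYPES",
    "MAJOR_NON_T_TYPES",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "pool_pseudobulk",
]

#: The 11 cell types distinguished by the pipeline.
CELL_TYPES: tuple[str, ...] = (
    "Malignant",
    "Fibroblast",
    "Macrophage",
    "Dendritic",
    "Endothelial",
    "Mast",
    "Bcell",
    "CD4Tconv",
    "Treg",
    "CD8Tconv",
    "CD8Texhausted",
)

#: The four T-cell subtypes resolved at the final identification stage.
T_SUBTYPES: tuple[str, ...] = ("CD4Tconv", "Treg", "CD8Tconv", "CD8Texhausted")

#: Major non-T immune/stromal types resolved at the second stage.
MAJOR_NON_T_TYPES: tuple[str, ...] = (
    "Fibroblast",
    "Macrophage",
    "Dendritic",
    "Endothelial",
    "Mast",
    "Bcell",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    All expression-scale parameters are in log2(TPM+1) units.

    ``marker_log2fc`` is the elevation of a type's planted markers above the
    shared baseline; ``patient_shift_sd`` is the standard deviation of the
    per-patient offset applied to malignant cells only; ``noise_sd`` is the
    per-cell, per-gene Gaussian noise; ``dropout_rate`` is the probability
    that any entry is zeroed.
    """

    n_patients: int = 16
    cells_per_patient: int = 300
    cell_types: tuple[str, ...] = CELL_TYPES
    malignant_fraction_range: tuple[float, float] = (0.0, 1.0)
    n_genes: int = 1200
    n_markers_per_type: int = 20
    marker_log2fc: float = 4.0
    patient_shift_sd: float = 1.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.malignant_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("malignant_fraction_range must be within [0, 1]")
        for name in ("n_patients", "cells_per_patient", "n_genes", "n_markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_genes < len(self.cell_types) * self.n_markers_per_type:
            raise ValueError(
                "n_genes must be >= n_types * n_markers_per_type so that "
                "planted marker sets can be disjoint"
            )
        if "Malignant" not in self.cell_types:
            raise ValueError("cell_types must include 'Malignant'")


@dataclass
class SyntheticDataset:
    """A generated cohort together with its ground truth."""

    expression: ExpressionMatrix
    truth_labels: pd.Series  # cell id -> cell type
    patient_ids: pd.Series  # cell id -> patient id
    true_fractions: pd.DataFrame  # patients x cell types, rows sum to 1
    planted_markers: dict[str, list[str]]
    config: SimulationConfig

    def __post_init__(self) -> None:
        sums = self.true_fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("true_fractions rows must each sum to 1")
        counts = (
            pd.crosstab(self.patient_ids, self.truth_labels)
            .reindex(index=self.true_fractions.index, columns=self.true_fractions.columns)
            .fillna(0)
        )
        frac = counts.div(counts.sum(axis=1), axis=0)
        if not np.allclose(frac.to_numpy(), self.true_fractions.to_numpy(), atol=1e-9):
            raise ValueError("true_fractions must match per-cell label counts")
        all_markers = [g for genes in self.planted_markers.values() for g in genes]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("planted marker sets must be disjoint")

    def signature_sets(self) -> GeneSetCollection:
        """Planted markers as a signature collection (the C1-style panel)."""
        return GeneSetCollection(
            {t: list(g) for t, g in self.planted_markers.items()}, source_tag="C1"
        )

    def write(self, outdir) -> None:
        """Write expression TSV, annotation CSV and marker GMT to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(self.expression, outdir / "expression.tsv")
        ann = pd.DataFrame(
            {"patient_id": self.patient_ids, "cell_type": self.truth_labels}
        )
        ann.index.name = "cell_id"
        write_annotation_csv(ann, outdir / "annotation.csv")
        write_gmt(self.signature_sets(), outdir / "markers.gmt")
        self.true_fractions.to_csv(outdir / "true_fractions.csv", index_label="patient_id")


def _stratified_fractions(n: int, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """One draw per equal-width stratum of [lo, hi], shuffled across patients.

    Guarantees the empirical fractions cover the range with max gap < 2/n
    (each stratum of width (hi-lo)/n holds exactly one draw).
    """
    u = rng.random(n)
    f = lo + (hi - lo) * (np.arange(n) + u) / n
    rng.shuffle(f)
    return f


def _integer_counts(target: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of fractional targets to integers summing to total."""
    raw = target * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a reproducible synthetic cohort.

    Per-cell profiles in log2(TPM+1) units are built as
    ``baseline + marker boost + patient shift (malignant only) + noise``,
    then subjected to dropout (random zeroing) and clipped at zero.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.cell_types)
    n_types = len(types)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    marker_pos = rng.permutation(cfg.n_genes)[: n_types * cfg.n_markers_per_type]
    planted = {
        t: [genes[j] for j in marker_pos[i * cfg.n_markers_per_type : (i + 1) * cfg.n_markers_per_type]]
        for i, t in enumerate(types)
    }

    baseline = np.clip(rng.normal(1.5, 1.0, cfg.n_genes), 0.0, None)
    boost = np.zeros((cfg.n_genes, n_types))
    for i, t in enumerate(types):
        idx = marker_pos[i * cfg.n_markers_per_type : (i + 1) * cfg.n_markers_per_type]
        boost[idx, i] = cfg.marker_log2fc

    lo, hi = cfg.malignant_fraction_range
    malignant_frac = _stratified_fractions(cfg.n_patients, lo, hi, rng)
    malig_idx = types.index("Malignant")
    other_idx = [i for i in range(n_types) if i != malig_idx]

    patients = [f"P{p:02d}" for p in range(cfg.n_patients)]
    counts = np.zeros((cfg.n_patients, n_types), dtype=int)
    for p in range(cfg.n_patients):
        n_mal = int(round(malignant_frac[p] * cfg.cells_per_patient))
        n_mal = min(max(n_mal, 0), cfg.cells_per_patient)
        rest = rng.dirichlet(np.ones(len(other_idx)))
        counts[p, malig_idx] = n_mal
        counts[p, other_idx] = _integer_counts(rest, cfg.cells_per_patient - n_mal)

    patient_shift = rng.normal(0.0, cfg.patient_shift_sd, (cfg.n_patients, cfg.n_genes))

    cell_ids: list[str] = []
    cell_type_idx: list[int] = []
    cell_patient_idx: list[int] = []
    for p in range(cfg.n_patients):
        c = 0
        for i in range(n_types):
            for _ in range(counts[p, i]):
                cell_ids.append(f"{patients[p]}_C{c:04d}")
                cell_type_idx.append(i)
                cell_patient_idx.append(p)
                c += 1
    n_cells = len(cell_ids)
    cell_type_idx = np.asarray(cell_type_idx)
    cell_patient_idx = np.asarray(cell_patient_idx)

    y = baseline[:, None] + boost[:, cell_type_idx]
    is_mal = cell_type_idx == malig_idx
    if is_mal.any():
        y[:, is_mal] += patient_shift[cell_patient_idx[is_mal]].T
    y += rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_cells))
    if cfg.dropout_rate > 0:
        y[rng.random((cfg.n_genes, n_cells)) < cfg.dropout_rate] = 0.0
    np.clip(y, 0.0, None, out=y)

    expr = ExpressionMatrix(
        pd.DataFrame(y, index=genes, columns=cell_ids), Scale.LOG2_TPM_PLUS1
    )
    labels = pd.Series([types[i] for i in cell_type_idx], index=cell_ids, name="cell_type")
    pats = pd.Series([patients[p] for p in cell_patient_idx], index=cell_ids, name="patient_id")
    fractions = pd.DataFrame(
        counts / counts.sum(axis=1, keepdims=True), index=patients, columns=types
    )
    return SyntheticDataset(expr, labels, pats, fractions, planted, cfg)


def pool_pseudobulk(ds: SyntheticDataset) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Pool each patient's cells into an in-silico bulk tumor.

    Single-cell values are un-logged to linear units (``2**y - 1``) and
    averaged gene-wise within each patient, so the exact mixing identity
    ``bulk = sum_k f_k * (mean linear profile of type k)`` holds by
    construction.  Returns the linear-scale pseudo-bulk matrix
    (genes x patients) and the per-patient cell-count fractions.
    """
    linear = ds.expression.to_linear().data
    cols: dict[str, np.ndarray] = {}
    kept: list[str] = []
    for patient in ds.true_fractions.index:
        cells = ds.patient_ids.index[ds.patient_ids == patient]
        if len(cells) == 0:
            warnings.warn(f"patient {patient} has no cells; skipped")
            continue
        cols[patient] = linear[cells].mean(axis=1).to_numpy()
        kept.append(patient)
    bulk = ExpressionMatrix(
        pd.DataFrame(cols, index=linear.index, columns=kept), Scale.LINEAR_TPM
    )
    return bulk, ds.true_fractions.loc[kept]
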