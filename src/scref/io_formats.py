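"""Readers, writers and the core in-memory containers.

Expression values follow the convention used throughout the pipeline:
``y = log2(TPM + 1)`` for single-cell matrices, linear TPM-like units for
pseudo-bulk mixtures and reference profiles.  Every consumer dispatches on
the explicit :class:`Scale` flag rather than guessing from the values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_gep_tsv",
    "write_gep_tsv",
    "to_linear",
    "to_log",
]


class Scale(str, Enum):
    """Units of an expression matrix."""

    LOG2_TPM_PLUS1 = "log2_tpm_plus1"
    LINEAR_TPM = "linear_tpm"


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix with an explicit unit flag.

    Parameters
    ----------
    data
        DataFrame with unique gene symbols as index and unique sample
        (cell) ids as columns.  Values must be finite and non-negative.
    scale
        Whether values are ``log2(TPM+1)`` or linear TPM-like units.
    """

    data: pd.DataFrame
    scale: Scale = Scale.LOG2_TPM_PLUS1

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene symbols: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains NaN or infinite values")
        if values.size and (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)][:5].tolist()
            raise ValueError(f"negative expression values in rows: {bad}")

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(ids)], self.scale)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale)

    def to_linear(self) -> "ExpressionMatrix":
        return to_linear(self)

    def to_log(self) -> "ExpressionMatrix":
        return to_log(self)


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert ``y = log2(TPM+1)`` values to linear ``x = 2**y - 1``.

    Idempotent when the matrix is already linear.
    """
    if m.scale is Scale.LINEAR_TPM:
        return m
    return ExpressionMatrix(np.exp2(m.data) - 1.0, Scale.LINEAR_TPM)


def to_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert linear values to ``y = log2(x + 1)``; idempotent on log data."""
    if m.scale is Scale.LOG2_TPM_PLUS1:
        return m
    return ExpressionMatrix(np.log2(m.data + 1.0), Scale.LOG2_TPM_PLUS1)


@dataclass
class GeneSetCollection:
    """Named signature gene sets (a parsed GMT file).

    ``sets`` maps set name -> ordered list of unique gene symbols.
    ``source_tag`` records panel provenance (e.g. ``"C1"``, ``"LM22"``).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        """Union of all sets, de-duplicated, first-occurrence order."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: list(self.sets[n]) for n in names}, self.source_tag)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path, scale: Scale | str = Scale.LOG2_TPM_PLUS1) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbols, header = ids).

    Duplicate gene rows are collapsed by taking the per-entry maximum (the
    collapse rule is intentional and tested).  NaN, negative values and
    ragged rows are rejected rather than coerced.
    """
    scale = Scale(scale)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"{path}: NaN/ragged entries in rows {bad}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:  # pragma: no cover - message path
        raise ValueError(f"{path}: non-numeric entries: {exc}") from exc
    if (df.to_numpy() < 0).any():
        bad = df.index[(df.to_numpy() < 0).any(axis=1)][:5].tolist()
        raise ValueError(f"{path}: negative values in rows {bad}")
    if df.index.has_duplicates:
        # keep first-occurrence gene order while collapsing by max
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).max().loc[order]
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, source_tag: str = "") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Empty gene fields are dropped; duplicate genes within one line are
    de-duplicated with a warning.  Lines with fewer than three fields are
    a parse error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                warnings.warn(f"{path}:{lineno}: {dups} duplicate gene(s) in set {name!r} dropped")
            sets[name] = genes
    return GeneSetCollection(sets, source_tag or Path(path).stem)


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# per-cell annotation CSV
# ---------------------------------------------------------------------------

def read_annotation_csv(path) -> pd.DataFrame:
    """Read a per-cell annotation table; requires at least cell_id, cell_type."""
    df = pd.read_csv(path, dtype=str)
    missing = {"cell_id", "cell_type"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids")
    return df.set_index("cell_id")


def write_annotation_csv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index_label="cell_id")


# ---------------------------------------------------------------------------
# reference GEP TSV (genes x cell types)
# ---------------------------------------------------------------------------

def read_gep_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any() or (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: GEP must be non-negative and NaN-free")
    return df


def write_gep_tsv(gep: pd.DataFrame, path) -> None:
    gep.to_csv(path, sep="\t", index_label="gene")
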