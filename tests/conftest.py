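"""Shared fixtures: synthetic cohorts, annotations, and independent oracles.

The oracle implementations here are deliberately written as plain literal
loops, independent of the package's vectorized code paths, so tests compare
two separately derived routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scref import SimulationConfig, StageConfig, annotate_cells, simulate_dataset


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic cohort (16 patients x 300 cells, 1200 genes)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_annotation(default_ds):
    """Full three-stage pipeline annotation of the default cohort."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_cells(
            default_ds.expression,
            default_ds.signature_sets(),
            StageConfig(seed=1),
            patient_ids=default_ds.patient_ids,
        )


@pytest.fixture()
def small_config():
    """A fast, small cohort configuration for unit tests."""
    return SimulationConfig(
        n_patients=6,
        cells_per_patient=80,
        n_genes=400,
        n_markers_per_type=8,
        seed=3,
    )


@pytest.fixture()
def small_ds(small_config):
    return simulate_dataset(small_config)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def literal_ssgsea_es(values, gene_names, set_genes, alpha):
    """Literal rank-weighted running-sum enrichment score for one sample.

    Walks the descending-expression gene list position by position (ties
    broken by gene symbol, rank weights averaged over ties) accumulating
    the weighted in-set and uniform out-of-set cumulative distributions.
    """
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], gene_names[i]))
    # average ascending rank (= N - position + 1 averaged over ties)
    by_value: dict[float, list[int]] = {}
    for i in range(n):
        by_value.setdefault(values[i], []).append(i)
    asc_rank = {}
    pos = 1
    for v in sorted(by_value):
        idxs = by_value[v]
        mean_rank = sum(range(pos, pos + len(idxs))) / len(idxs)
        for i in idxs:
            asc_rank[i] = mean_rank
        pos += len(idxs)
    in_set = [gene_names[i] in set_genes for i in order]
    k = sum(in_set)
    denom_in = sum(asc_rank[i] ** alpha for i in order if gene_names[i] in set_genes)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for step, i in enumerate(order):
        if gene_names[i] in set_genes:
            cum_in += asc_rank[i] ** alpha / denom_in
        else:
            cum_out += 1.0 / (n - k)
        es += cum_in - cum_out
    return es


def bh_oracle(p):
    """O(n^2) definitional Benjamini-Hochberg step-up adjustment.

    adj_i = min over j with p_(j) >= p_(i) of p_(j) * n / rank(j), capped at 1.
    """
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    ranked = [(rank + 1, p[i]) for rank, i in enumerate(order)]
    adj = [0.0] * n
    for i in range(n):
        candidates = [pj * n / rj for rj, pj in ranked if pj >= p[i]]
        adj[i] = min(1.0, min(candidates))
    return np.array(adj)


@pytest.fixture(scope="session")
def ssgsea_oracle():
    return literal_ssgsea_es


@pytest.fixture(scope="session")
def bh_definitional_oracle():
    return bh_oracle
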