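import numpy as np
import pytest

from scdebench.containers import CountMatrix, DEResult, SimTruth
from scdebench.de_methods import bh_adjust
from scdebench.preprocess import filter_genes
from scdebench.sim_splat import SplatParams, simulate_counts


def make_count_matrix(counts, batch=None, group=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if batch is None:
        batch = ["b1"] * n_cells
    if group is None:
        group = ["case"] * (n_cells // 2) + ["control"] * (n_cells - n_cells // 2)
    return CountMatrix(
        counts=counts,
        gene_ids=np.array([f"G{i:04d}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"C{j:04d}" for j in range(n_cells)], dtype=object),
        batch=np.array(batch, dtype=object),
        group=np.array(group, dtype=object),
    )


def make_de_result(p, logfc=None, sign=None, gene_ids=None, method="test"):
    p = np.asarray(p, dtype=float)
    n = p.size
    if gene_ids is None:
        gene_ids = np.array([f"G{i:04d}" for i in range(n)], dtype=object)
    if logfc is None:
        logfc = np.where(p < 0.5, 1.0, -1.0)
    if sign is None:
        sign = np.sign(logfc).astype(int)
    return DEResult(
        gene_ids=np.asarray(gene_ids, dtype=object),
        p_value=p,
        q_value=bh_adjust(p),
        logfc=np.asarray(logfc, dtype=float),
        sign=np.asarray(sign, dtype=int),
        method=method,
    )


def make_truth(status, gene_ids=None, effect=None):
    status = np.asarray(status, dtype=object)
    n = status.size
    if gene_ids is None:
        gene_ids = np.array([f"G{i:04d}" for i in range(n)], dtype=object)
    if effect is None:
        effect = np.where(status == "null", 1.0, 2.0)
    return SimTruth(
        gene_ids=np.asarray(gene_ids, dtype=object),
        status=status,
        effect=np.asarray(effect, dtype=float),
    )


@pytest.fixture(scope="session")
def small_splat():
    """Two-batch simulation with DE and batch effects, filtered (shared,
    read-only)."""
    params = SplatParams(
        n_genes=300, batch_sizes=[120, 180], libsize_loc=10.0, seed=7
    )
    counts, truth = simulate_counts(params)
    filtered = filter_genes(counts)
    return filtered, truth.subset(filtered.gene_ids)


@pytest.fixture(scope="session")
def null_splat():
    """No DE, no batch effects: a global-null fixture."""
    params = SplatParams(
        n_genes=400,
        batch_sizes=[100, 100],
        de_prob=0.0,
        batch_facLoc=0.0,
        batch_facScale=0.0,
        libsize_loc=10.0,
        dropout_mid=0.01,
        seed=13,
    )
    counts, truth = simulate_counts(params)
    filtered = filter_genes(counts)
    return filtered, truth.subset(filtered.gene_ids)
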