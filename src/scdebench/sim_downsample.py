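"""Model-free DE simulator: case/control split plus binomial downsampling.

Takes any real or synthetic count matrix, splits the cells of each batch
into case and control groups at a chosen ratio, picks two disjoint random
gene sets (default 10% of genes each) and reduces the positive counts of
one set in the case group and the other in the control group by binomial
thinning.  The per-gene binomial success probability is drawn from
Beta(2, 2), which yields DE genes with a median fold change near two.

A gene thinned in the case group is labelled "down" (lower in case); one
thinned in control is labelled "up".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    GROUP_CASE,
    GROUP_CONTROL,
    STATUS_DOWN,
    STATUS_NULL,
    STATUS_UP,
    CountMatrix,
    SimTruth,
)
from .preprocess import filter_genes

__all__ = [
    "DownsampleParams",
    "split_case_control",
    "select_de_genes",
    "downsample_counts",
    "simulate_downsample",
]


@dataclass
class DownsampleParams:
    """Parameters of the model-free simulator (defaults match the benchmark:
    20% DE genes, Beta(2,2) thinning probabilities)."""

    de_fraction: float = 0.2
    beta_alpha: float = 2.0
    beta_beta: float = 2.0
    group_ratio: float = 0.5
    seed: int = 0
    p_per_batch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ValueError("beta shape parameters must be strictly positive")
        if not 0.0 < self.group_ratio < 1.0:
            raise ValueError("group_ratio must lie in (0, 1)")


def split_case_control(
    cells: CountMatrix, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Random case/control labels, stratified within each batch.

    Within each batch, ``round(ratio * n_cells_in_batch)`` cells become
    case; assignment is a uniform random permutation given ``rng``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    groups = np.empty(cells.n_cells, dtype=object)
    for b in cells.batches:
        idx = np.flatnonzero(cells.batch == b)
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
        n_case = int(round(ratio * len(idx)))
        perm = rng.permutation(idx)
        groups[perm[:n_case]] = GROUP_CASE
        groups[perm[n_case:]] = GROUP_CONTROL
    return groups


def select_de_genes(
    gene_ids: np.ndarray, params: DownsampleParams, rng: np.random.Generator
) -> SimTruth:
    """Pick disjoint up/down gene sets and draw their thinning probabilities.

    Each direction receives ``round(de_fraction / 2 * n_genes)`` genes (an
    odd total puts the extra gene in "up").  One Beta(alpha, beta) success
    probability is drawn per DE gene; null genes carry effect 1.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes = len(gene_ids)
    n_de = int(round(params.de_fraction * n_genes))
    if params.de_fraction > 0 and n_de < 2:
        raise ValueError("de_fraction too small: fewer than 2 DE genes")
    n_down = n_de // 2
    n_up = n_de - n_down

    status = np.full(n_genes, STATUS_NULL, dtype=object)
    effect = np.ones(n_genes)
    if n_de > 0:
        chosen = rng.permutation(n_genes)[:n_de]
        status[chosen[:n_up]] = STATUS_UP
        status[chosen[n_up:]] = STATUS_DOWN
        effect[chosen] = rng.beta(params.beta_alpha, params.beta_beta, size=n_de)
    return SimTruth(
        gene_ids=gene_ids, status=status, effect=effect, provenance="model_free"
    )


def downsample_counts(
    counts: CountMatrix,
    truth: SimTruth,
    groups: np.ndarray,
    rng: np.random.Generator,
) -> CountMatrix:
    """Binomially thin DE genes in their targeted group.

    "down" genes are thinned in the case group, "up" genes in the control
    group; every count c of a targeted (gene, cell) entry is replaced by
    Binomial(c, p) with the gene's success probability p.  All other
    entries are returned bit-identical.
    """
    idx = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in truth.gene_ids if g not in idx]
    if missing:
        raise KeyError(f"truth genes absent from matrix: {missing[:5]}")
    groups = np.asarray(groups, dtype=object)
    new_counts = counts.counts.copy()
    case_mask = groups == GROUP_CASE
    ctrl_mask = groups == GROUP_CONTROL
    for gene, status, p in zip(truth.gene_ids, truth.status, truth.effect):
        if status == STATUS_NULL:
            continue
        if not 0.0 < p <= 1.0:
            raise ValueError(f"success probability for {gene} outside (0, 1]")
        target = case_mask if status == STATUS_DOWN else ctrl_mask
        row = idx[gene]
        new_counts[row, target] = rng.binomial(new_counts[row, target], p)
    return CountMatrix(
        counts=new_counts,
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        batch=counts.batch,
        group=groups,
    )


def simulate_downsample(
    source: CountMatrix,
    params: DownsampleParams,
    max_zero_rate: float = 0.95,
) -> tuple[CountMatrix, SimTruth]:
    """End-to-end model-free simulation from a source count matrix.

    Applies the sparse-gene filter to the source, splits each batch into
    case/control at ``params.group_ratio``, selects DE genes and thins
    them.  Any pre-existing group labels on the source are ignored.
    """
    rng = np.random.default_rng(params.seed)
    filtered = filter_genes(source, max_zero_rate=max_zero_rate)
    groups = split_case_control(filtered, params.group_ratio, rng)
    truth = select_de_genes(filtered.gene_ids, params, rng)
    simulated = downsample_counts(filtered, truth, groups, rng)
    return simulated, truth
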