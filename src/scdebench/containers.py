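"""Core in-memory containers shared by the simulators, DE methods and metrics.

The universal input is a gene x cell integer count matrix with per-cell
batch and group labels (:class:`CountMatrix`).  Simulators additionally emit
a per-gene ground truth (:class:`SimTruth`), DE procedures emit a common
per-gene result schema (:class:`DEResult`), and rank-based evaluation uses
weighted standard-positive gene sets (:class:`WeightedGeneSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_CASE = "case"
GROUP_CONTROL = "control"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NULL = "null"


@dataclass
class CountMatrix:
    """Gene x cell integer counts with per-cell batch and group labels.

    Parameters
    ----------
    counts
        2-D integer array of shape ``(n_genes, n_cells)``, entries >= 0.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    batch
        Per-cell batch label (technical origin of the cell).
    group
        Per-cell biological condition, ``"case"`` or ``"control"``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    batch: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        for name, arr in (
            ("cell_ids", self.cell_ids),
            ("batch", self.batch),
            ("group", self.group),
        ):
            if len(arr) != n_cells:
                raise ValueError(f"{name} length does not match counts columns")
        if len(np.unique(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def lib_size(self) -> np.ndarray:
        """Per-cell total count over the genes currently retained."""
        return self.counts.sum(axis=0)

    @property
    def batches(self) -> list:
        """Distinct batch labels in order of first appearance."""
        return list(pd.unique(self.batch))

    def group_mask(self, group: str) -> np.ndarray:
        return self.group == group

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Row subset preserving gene order; library sizes follow automatically."""
        keep = np.asarray(keep)
        return CountMatrix(
            counts=self.counts[keep],
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            batch=self.batch,
            group=self.group,
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            batch=self.batch[keep],
            group=self.group[keep],
        )

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "batch": self.batch, "group": self.group}
        )


@dataclass
class SimTruth:
    """Per-gene differential-expression ground truth from a simulator.

    ``status`` is the direction of the gene in case relative to control
    (``"up"``, ``"down"`` or ``"null"``).  ``effect`` is the generative
    effect: a multiplicative fold factor for the model-based simulator
    (exactly 1 for null genes) or the binomial success probability for the
    model-free downsampler.
    """

    gene_ids: np.ndarray
    status: np.ndarray
    effect: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.status = np.asarray(self.status, dtype=object)
        self.effect = np.asarray(self.effect, dtype=float)
        if not (len(self.gene_ids) == len(self.status) == len(self.effect)):
            raise ValueError("truth arrays must have equal length")
        bad = set(np.unique(self.status)) - {STATUS_UP, STATUS_DOWN, STATUS_NULL}
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def de_mask(self) -> np.ndarray:
        return self.status != STATUS_NULL

    def direction_mask(self, direction: str) -> np.ndarray:
        if direction not in (STATUS_UP, STATUS_DOWN):
            raise ValueError("direction must be 'up' or 'down'")
        return self.status == direction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "status": self.status, "effect": self.effect}
        )

    def subset(self, gene_ids: np.ndarray) -> "SimTruth":
        """Restrict truth to the given genes (e.g. after filtering)."""
        idx = pd.Index(self.gene_ids).get_indexer(np.asarray(gene_ids, dtype=object))
        if (idx < 0).any():
            raise KeyError("some requested genes absent from truth")
        return SimTruth(
            gene_ids=self.gene_ids[idx],
            status=self.status[idx],
            effect=self.effect[idx],
            provenance=self.provenance,
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression values: ``log_base(c / L * scale + 1)``."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    batch: np.ndarray
    group: np.ndarray
    scale_factor: float = 1e4
    log_base: float = 2.0
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        if self.provenance == "raw" and (self.values < 0).any():
            raise ValueError("raw log-normalized values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return self.group == group


@dataclass
class DEResult:
    """Common per-gene output schema of every DE procedure and adapter."""

    gene_ids: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    logfc: np.ndarray
    sign: np.ndarray
    method: str = "unknown"
    se: np.ndarray | None = None  # per-gene standard error, where the test provides one

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.q_value = np.asarray(self.q_value, dtype=float)
        self.logfc = np.asarray(self.logfc, dtype=float)
        self.sign = np.asarray(self.sign, dtype=int)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        n = len(self.gene_ids)
        for name, arr in (
            ("p_value", self.p_value),
            ("q_value", self.q_value),
            ("logfc", self.logfc),
            ("sign", self.sign),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match gene_ids")
        finite_p = self.p_value[np.isfinite(self.p_value)]
        if ((finite_p < 0) | (finite_p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if not np.isin(self.sign, [-1, 0, 1]).all():
            raise ValueError("sign must be -1, 0 or +1")

    @property
    def n_genes_tested(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "logfc": self.logfc,
                "pvalue": self.p_value,
                "qvalue": self.q_value,
                "sign": self.sign,
                "method": self.method,
            }
        )


@dataclass
class WeightedGeneSet:
    """Standard-positive genes with nonnegative association weights.

    Genes absent from the mapping carry weight 0.  Mirrors disease-gene sets
    weighted by gene-disease association scores.
    """

    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for gene, w in self.weights.items():
            w = float(w)
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for {gene} must be finite and >= 0")
            clean[str(gene)] = w
        if not any(w > 0 for w in clean.values()):
            raise ValueError("at least one positive weight required")
        self.weights = clean

    def weight_vector(self, gene_ids: np.ndarray) -> np.ndarray:
        return np.array([self.weights.get(str(g), 0.0) for g in gene_ids])

    @property
    def genes(self) -> list:
        return [g for g, w in self.weights.items() if w > 0]
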