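"""Reading and writing the on-disk exchange formats.

Count matrices travel as Matrix Market (genes x cells, integer field) with
``genes.tsv`` / ``cells.tsv`` sidecars; simulation truth, DE results and
weighted gene sets are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, DEResult, SimTruth, WeightedGeneSet

DE_RESULT_COLUMNS = ["gene_id", "logfc", "pvalue", "qvalue", "sign", "method"]


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> None:
    """Write ``matrix.mtx`` plus ``genes.tsv`` and ``cells.tsv`` sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse, field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cm.cells_frame().to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_count_matrix(
    matrix: str | Path,
    cells: str | Path | None = None,
    genes: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (or dense CSV/TSV) plus metadata sidecars.

    When ``matrix`` points into a directory written by
    :func:`write_count_matrix`, the sidecar paths default to the files next
    to it.
    """
    matrix = Path(matrix)
    if matrix.is_dir():
        matrix = matrix / "matrix.mtx"
    if cells is None:
        cells = matrix.parent / "cells.tsv"
    if genes is None:
        genes = matrix.parent / "genes.tsv"

    if matrix.suffix == ".mtx":
        counts = np.asarray(scipy.io.mmread(str(matrix)).todense())
    else:
        sep = "," if matrix.suffix == ".csv" else "\t"
        counts = pd.read_csv(matrix, sep=sep, header=None).to_numpy()
    gene_df = pd.read_csv(genes, sep="\t", keep_default_na=False)
    cell_df = pd.read_csv(cells, sep="\t", keep_default_na=False)
    for col in ("cell_id", "batch", "group"):
        if col not in cell_df.columns:
            raise ValueError(f"cells metadata missing required column '{col}'")
    return CountMatrix(
        counts=counts,
        gene_ids=gene_df["gene_id"].to_numpy(),
        cell_ids=cell_df["cell_id"].to_numpy(),
        batch=cell_df["batch"].to_numpy(),
        group=cell_df["group"].to_numpy(),
    )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path, provenance: str = "file") -> SimTruth:
    # keep_default_na: the literal status label "null" must stay a string
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return SimTruth(
        gene_ids=df["gene_id"].to_numpy(),
        status=df["status"].to_numpy(),
        effect=df["effect"].to_numpy(),
        provenance=provenance,
    )


def write_de_result(result: DEResult, path: str | Path) -> None:
    result.to_frame()[DE_RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_geneset(path: str | Path) -> WeightedGeneSet:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "weight"} <= set(df.columns):
        raise ValueError("gene set TSV requires columns gene_id, weight")
    return WeightedGeneSet(dict(zip(df["gene_id"].astype(str), df["weight"])))


def write_geneset(geneset: WeightedGeneSet, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(geneset.weights), "weight": list(geneset.weights.values())}
    ).to_csv(path, sep="\t", index=False)
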