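"""Gene filtering, log-normalization and nonzero-mean logFC estimation.

These three steps are shared by the simulators, the native DE methods and
the evaluation metrics:

* genes expressed in too few cells (zero rate above ``max_zero_rate``,
  default 0.95) are removed before any analysis;
* counts are log-normalized as ``log_base(c / L * 10^4 + 1)`` with ``L`` the
  cell library size over retained genes;
* per-gene logFC is the difference of mean log-normalized expression over
  *nonzero* cells, case minus control, with degenerate genes flagged
  rather than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    GROUP_CASE,
    GROUP_CONTROL,
    CountMatrix,
    NormalizedMatrix,
)

FLAG_OK = "ok"
FLAG_CASE_ALL_ZERO = "case_all_zero"
FLAG_CONTROL_ALL_ZERO = "control_all_zero"
FLAG_BOTH_ZERO = "both_zero"


def filter_genes(counts: CountMatrix, max_zero_rate: float = 0.95) -> CountMatrix:
    """Drop genes whose fraction of zero cells exceeds ``max_zero_rate``.

    Gene order is preserved and library sizes are recomputed over the
    retained genes.  Idempotent: filtering a filtered matrix changes
    nothing.
    """
    if not 0.0 < max_zero_rate < 1.0:
        raise ValueError("max_zero_rate must lie in (0, 1)")
    zero_rate = (counts.counts == 0).mean(axis=1)
    keep = zero_rate <= max_zero_rate
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return counts.subset_genes(keep)


def log_normalize(
    counts: CountMatrix,
    scale: float = 1e4,
    base: float = 2.0,
    lib_size: np.ndarray | None = None,
) -> NormalizedMatrix:
    """Library-size log-normalization ``log_base(c / L * scale + 1)``.

    ``lib_size`` overrides the per-cell totals (e.g. to use pre-filter
    library sizes); by default the current column sums are used.
    """
    L = counts.lib_size if lib_size is None else np.asarray(lib_size)
    if (L <= 0).any():
        bad = counts.cell_ids[np.asarray(L) <= 0][:5]
        raise ValueError(f"cells with zero library size: {list(bad)}")
    values = np.log1p(counts.counts / L[None, :] * scale) / np.log(base)
    return NormalizedMatrix(
        values=values,
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        batch=counts.batch,
        group=counts.group,
        scale_factor=scale,
        log_base=base,
        provenance="raw",
    )


def estimate_logfc(
    norm: NormalizedMatrix,
    groups: np.ndarray | None = None,
    nonzero_only: bool = True,
) -> pd.DataFrame:
    """Per-gene logFC: mean log-normalized expression, case minus control.

    By default the mean runs over cells with nonzero expression only; genes
    with no nonzero cell in one group report non-finite logFC and an
    explanatory flag.  Setting ``nonzero_only=False`` switches to the
    all-cell mean for sensitivity analysis.

    Returns a DataFrame with columns ``gene_id``, ``logfc``,
    ``n_nonzero_case``, ``n_nonzero_control``, ``flag``.
    """
    groups = norm.group if groups is None else np.asarray(groups, dtype=object)
    case_mask = groups == GROUP_CASE
    ctrl_mask = groups == GROUP_CONTROL
    if not case_mask.any() or not ctrl_mask.any():
        raise ValueError("both case and control groups must be nonempty")

    values = norm.values
    case_vals = values[:, case_mask]
    ctrl_vals = values[:, ctrl_mask]
    nz_case = (case_vals != 0).sum(axis=1)
    nz_ctrl = (ctrl_vals != 0).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        if nonzero_only:
            mean_case = case_vals.sum(axis=1) / nz_case
            mean_ctrl = ctrl_vals.sum(axis=1) / nz_ctrl
        else:
            mean_case = case_vals.mean(axis=1)
            mean_ctrl = ctrl_vals.mean(axis=1)
        logfc = mean_case - mean_ctrl

    flag = np.full(norm.n_genes, FLAG_OK, dtype=object)
    if nonzero_only:
        flag[nz_case == 0] = FLAG_CASE_ALL_ZERO
        flag[nz_ctrl == 0] = FLAG_CONTROL_ALL_ZERO
        flag[(nz_case == 0) & (nz_ctrl == 0)] = FLAG_BOTH_ZERO
        logfc = np.where(flag == FLAG_OK, logfc, np.nan)

    return pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "logfc": logfc,
            "n_nonzero_case": nz_case,
            "n_nonzero_control": nz_ctrl,
            "flag": flag,
        }
    )
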