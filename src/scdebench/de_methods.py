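"""Native differential-expression procedures and the external-result adapter.

Implemented natively:

* Wilcoxon rank-sum test on log-normalized data (the most widely used
  scRNA-seq DE test);
* a per-gene negative-binomial count GLM with log library size and,
  optionally, batch indicators as covariates, testing the case/control
  coefficient (the "covariate model");
* pseudobulk aggregation (summing cells per batch x group unit or per
  sample) followed by a two-sample test on log-CPM;
* meta-analysis: per-batch DE followed by weighted Fisher p-value
  combination or inverse-variance fixed/random effects pooling of effect
  sizes.

DE engines and batch-effect-correction methods that belong to other
ecosystems are ingested through :func:`read_external_result` rather than
reimplemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .containers import (
    GROUP_CASE,
    GROUP_CONTROL,
    CountMatrix,
    DEResult,
    NormalizedMatrix,
)
from .preprocess import estimate_logfc, filter_genes, log_normalize

__all__ = [
    "bh_adjust",
    "signed_score",
    "wilcoxon_de",
    "lognorm_ttest_de",
    "covariate_glm_de",
    "pseudobulk_aggregate",
    "pseudobulk_de",
    "MetaConfig",
    "meta_combine",
    "meta_de",
    "read_external_result",
]

_P_FLOOR = 1e-300


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[valid] = out
    return q


def signed_score(result: DEResult, log_base: float = 10.0) -> np.ndarray:
    """Per-gene signed log-p score: ``-log(p) * sign(logFC)``.

    Zero p-values are clamped to 1e-300 before taking logs.  Ranks (and
    hence Spearman similarities) do not depend on the log base.
    """
    p = np.clip(result.p_value, _P_FLOOR, 1.0)
    return -np.log(p) / np.log(log_base) * result.sign


def _signs_from_logfc(logfc: np.ndarray) -> np.ndarray:
    sign = np.sign(np.nan_to_num(logfc, nan=0.0))
    return sign.astype(int)


def wilcoxon_de(
    norm: NormalizedMatrix, groups: np.ndarray | None = None
) -> DEResult:
    """Two-sided Wilcoxon rank-sum test per gene on log-normalized values.

    Uses the tie-corrected normal approximation (exact enumeration at tiny
    tie-free sample sizes); the reported sign comes from the nonzero-mean
    logFC convention.  Genes constant across all cells get p = 1, sign 0.
    """
    groups = norm.group if groups is None else np.asarray(groups, dtype=object)
    case = norm.values[:, groups == GROUP_CASE]
    ctrl = norm.values[:, groups == GROUP_CONTROL]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("both groups need at least 2 cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            case, ctrl, axis=1, alternative="two-sided", method="auto"
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(norm.values, axis=1) == 0
    p[constant | np.isnan(p)] = 1.0

    lf = estimate_logfc(norm, groups)
    logfc = lf["logfc"].to_numpy()
    sign = _signs_from_logfc(logfc)
    sign[constant] = 0
    return DEResult(
        gene_ids=norm.gene_ids,
        p_value=p,
        q_value=bh_adjust(p),
        logfc=logfc,
        sign=sign,
        method="wilcoxon",
    )


def lognorm_ttest_de(
    norm: NormalizedMatrix, groups: np.ndarray | None = None
) -> DEResult:
    """Welch t-test per gene on log-normalized values (all cells).

    Effect size is the difference of group means with its Welch standard
    error, making this the natural within-batch engine for fixed- and
    random-effects meta-analysis of log-normalized data.
    """
    groups = norm.group if groups is None else np.asarray(groups, dtype=object)
    case = norm.values[:, groups == GROUP_CASE]
    ctrl = norm.values[:, groups == GROUP_CONTROL]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("both groups need at least 2 cells")
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    se = np.sqrt(se2)
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(t)
    p[degenerate] = 1.0
    sign = _signs_from_logfc(effect)
    sign[degenerate & (effect == 0)] = 0
    return DEResult(
        gene_ids=norm.gene_ids,
        p_value=p,
        q_value=bh_adjust(p),
        logfc=effect,
        sign=sign,
        method="lognorm_ttest",
        se=np.where(np.isfinite(se) & (se > 0), se, np.nan),
    )


def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion from a Poisson fit."""
    denom = float((mu**2).sum())
    if denom <= 0:
        return 1e-8
    alpha = float(((y - mu) ** 2 - mu).sum() / denom)
    return float(np.clip(alpha, 1e-8, 10.0))


def covariate_glm_de(
    counts: CountMatrix,
    include_batch: bool = True,
    test: str = "wald",
    libsize_as: str = "covariate",
) -> tuple[DEResult, pd.DataFrame]:
    """Per-gene NB count GLM with group, library-size and batch covariates.

    Fits ``log E(y_ij) = a0 + a1 log L_j + sum_b beta_b I_jb + gamma I_j,case``
    per gene (NB family, log link) and tests ``gamma = 0``.  With
    ``include_batch=False`` the batch block is dropped (the naive pooled
    model).  ``libsize_as="offset"`` fixes the library-size coefficient at 1
    instead of estimating it.  ``test`` is ``"wald"`` (default) or
    ``"lrt"``.

    Returns the DE result plus a per-gene coefficient table.  Genes whose
    fit fails (separation, singular design) are flagged with p = 1.
    """
    if test not in ("wald", "lrt"):
        raise ValueError("test must be 'wald' or 'lrt'")
    if libsize_as not in ("covariate", "offset"):
        raise ValueError("libsize_as must be 'covariate' or 'offset'")
    batches = counts.batches
    if include_batch:
        for b in batches:
            in_b = counts.batch == b
            present = set(counts.group[in_b])
            if present != {GROUP_CASE, GROUP_CONTROL}:
                raise ValueError(
                    f"batch {b!r} does not contain both groups; "
                    "covariate modeling requires a balanced design"
                )

    L = counts.lib_size.astype(float)
    if (L <= 0).any():
        raise ValueError("cells with zero library size")
    log_L = np.log(L)
    group_ind = (counts.group == GROUP_CASE).astype(float)

    cols = [np.ones(counts.n_cells)]
    names = ["intercept"]
    offset = None
    if libsize_as == "covariate":
        cols.append(log_L)
        names.append("log_libsize")
    else:
        offset = log_L
    if include_batch and len(batches) > 1:
        for b in batches[1:]:  # first batch is the reference level
            cols.append((counts.batch == b).astype(float))
            names.append(f"batch[{b}]")
    cols.append(group_ind)
    names.append("group")
    X = np.column_stack(cols)
    gamma_idx = len(names) - 1
    X_null = np.delete(X, gamma_idx, axis=1)

    n_genes = counts.n_genes
    pvals = np.ones(n_genes)
    gammas = np.zeros(n_genes)
    stats = np.zeros(n_genes)
    flags = np.zeros(n_genes, dtype=bool)
    coef_rows = np.full((n_genes, len(names)), np.nan)
    alphas = np.full(n_genes, np.nan)

    for i in range(n_genes):
        y = counts.counts[i].astype(float)
        if np.ptp(y) == 0:
            flags[i] = True
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(
                    y, X, family=sm.families.Poisson(), offset=offset
                ).fit(maxiter=50)
                alpha = _estimate_nb_alpha(y, pois.fittedvalues)
                fam = sm.families.NegativeBinomial(alpha=alpha)
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
                if test == "wald":
                    z = fit.params[gamma_idx] / fit.bse[gamma_idx]
                    p = 2.0 * scipy.stats.norm.sf(abs(z))
                    stat = z
                else:
                    fit0 = sm.GLM(y, X_null, family=fam, offset=offset).fit(
                        maxiter=100
                    )
                    stat = 2.0 * (fit.llf - fit0.llf)
                    p = scipy.stats.chi2.sf(max(stat, 0.0), df=1)
            if not np.isfinite(p):
                raise FloatingPointError("non-finite p-value")
            pvals[i] = p
            gammas[i] = fit.params[gamma_idx]
            stats[i] = stat
            coef_rows[i] = fit.params
            alphas[i] = alpha
        except Exception:
            flags[i] = True

    # report gamma on the log2 scale to match the logFC convention
    logfc = gammas / np.log(2.0)
    sign = _signs_from_logfc(logfc)
    sign[flags] = 0
    pvals[flags] = 1.0
    method = "glm_cov" if include_batch else "glm"
    result = DEResult(
        gene_ids=counts.gene_ids,
        p_value=pvals,
        q_value=bh_adjust(pvals),
        logfc=logfc,
        sign=sign,
        method=method,
    )
    fit_table = pd.DataFrame(coef_rows, columns=names)
    fit_table.insert(0, "gene_id", counts.gene_ids)
    fit_table["dispersion"] = alphas
    fit_table["statistic"] = stats
    fit_table["pvalue"] = pvals
    fit_table["fit_failed"] = flags
    return result, fit_table


def pseudobulk_aggregate(
    counts: CountMatrix, unit: str | np.ndarray = "batch_group"
) -> CountMatrix:
    """Sum single-cell counts into pseudobulk units.

    ``unit="batch_group"`` forms one unit per batch x group combination;
    alternatively pass an explicit per-cell sample label array (each sample
    must be group-homogeneous).  Each group needs at least two units for
    downstream testing.
    """
    if isinstance(unit, str):
        if unit != "batch_group":
            raise ValueError("unit must be 'batch_group' or a per-cell label array")
        labels = np.array(
            [f"{b}|{g}" for b, g in zip(counts.batch, counts.group)], dtype=object
        )
    else:
        labels = np.asarray(unit, dtype=object)
        if len(labels) != counts.n_cells:
            raise ValueError("unit labels must match the number of cells")
    unit_names = list(pd.unique(labels))
    sums = np.empty((counts.n_genes, len(unit_names)), dtype=np.int64)
    unit_batch, unit_group = [], []
    for k, u in enumerate(unit_names):
        mask = labels == u
        sums[:, k] = counts.counts[:, mask].sum(axis=1)
        groups_here = set(counts.group[mask])
        if len(groups_here) != 1:
            raise ValueError(f"pseudobulk unit {u!r} mixes case and control cells")
        unit_group.append(groups_here.pop())
        batches_here = set(counts.batch[mask])
        unit_batch.append(batches_here.pop() if len(batches_here) == 1 else "mixed")
    unit_group = np.array(unit_group, dtype=object)
    for g in (GROUP_CASE, GROUP_CONTROL):
        if (unit_group == g).sum() < 2:
            raise ValueError(
                f"group {g!r} has fewer than 2 pseudobulk units (no replication)"
            )
    return CountMatrix(
        counts=sums,
        gene_ids=counts.gene_ids,
        cell_ids=np.array(unit_names, dtype=object),
        batch=np.array(unit_batch, dtype=object),
        group=unit_group,
    )


def pseudobulk_de(bulk: CountMatrix, paired_by_batch: bool = False) -> DEResult:
    """Two-sample test on log-CPM of pseudobulk units.

    Default is an unpaired two-sided t-test per gene; ``paired_by_batch``
    pairs case and control units within each batch (requires exactly one
    unit per batch x group).
    """
    L = bulk.lib_size.astype(float)
    logcpm = np.log2(bulk.counts / L[None, :] * 1e6 + 1.0)
    case = logcpm[:, bulk.group == GROUP_CASE]
    ctrl = logcpm[:, bulk.group == GROUP_CONTROL]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("fewer than 2 units per group")
    if paired_by_batch:
        case_order = np.argsort(bulk.batch[bulk.group == GROUP_CASE].astype(str))
        ctrl_order = np.argsort(bulk.batch[bulk.group == GROUP_CONTROL].astype(str))
        if case.shape[1] != ctrl.shape[1]:
            raise ValueError("paired test requires one unit per batch and group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = scipy.stats.ttest_rel(case[:, case_order], ctrl[:, ctrl_order], axis=1)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = scipy.stats.ttest_ind(case, ctrl, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    p[np.isnan(p)] = 1.0
    sign = _signs_from_logfc(effect)
    return DEResult(
        gene_ids=bulk.gene_ids,
        p_value=p,
        q_value=bh_adjust(p),
        logfc=effect,
        sign=sign,
        method="pseudobulk_paired" if paired_by_batch else "pseudobulk",
    )


@dataclass
class MetaConfig:
    """Configuration of the per-batch meta-analysis.

    ``weights`` gives one positive weight per batch, in batch order (a
    mapping's values are taken in insertion order); when omitted, batch
    cell counts are used.  ``engine`` names the within-batch DE procedure
    (fixed/random effects require one that reports standard errors).
    """

    combiner: str = "weighted_fisher"
    weights: dict | list | None = None
    engine: str = "lognorm_ttest"

    def __post_init__(self) -> None:
        if self.combiner not in ("weighted_fisher", "fixed_effects", "random_effects"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.weights is not None:
            vals = (
                list(self.weights.values())
                if isinstance(self.weights, dict)
                else list(self.weights)
            )
            if any(w <= 0 for w in vals):
                raise ValueError("weights must be positive")

    def weight_vector(self, n_batches: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(n_batches)
        vals = (
            list(self.weights.values())
            if isinstance(self.weights, dict)
            else list(self.weights)
        )
        if len(vals) != n_batches:
            raise ValueError("number of weights must match number of batches")
        return np.asarray(vals, dtype=float)


def _one_sided(p: np.ndarray, sign: np.ndarray, direction: int) -> np.ndarray:
    """Convert two-sided p plus sign into the one-sided p for a direction."""
    half = p / 2.0
    out = np.where(sign == direction, half, 1.0 - half)
    out[sign == 0] = 0.5
    return out


def _weighted_fisher(p_one: np.ndarray, w: np.ndarray) -> float:
    """Combine one-sided p-values with gamma-reparameterized weights.

    Weights are normalized to sum to the number of studies; each p maps to
    an upper Gamma(w_k, 2) quantile and the sum is referred to
    Gamma(sum w, 2).  Equal weights reduce to Fisher's chi-square method.
    """
    w = w / w.sum() * len(w)
    stat = scipy.stats.gamma.isf(np.clip(p_one, _P_FLOOR, 1.0), a=w, scale=2.0).sum()
    return float(scipy.stats.gamma.sf(stat, a=w.sum(), scale=2.0))


def meta_combine(per_batch: list[DEResult], config: MetaConfig | None = None) -> DEResult:
    """Combine per-batch DE results into a single result.

    ``weighted_fisher`` combines one-sided p-values in both directions with
    batch-size weights, takes the smaller of the two combined values,
    doubles it (capped at 1) and assigns the corresponding sign.
    ``fixed_effects`` / ``random_effects`` pool per-batch effects by
    inverse variance (random effects adds a DerSimonian-Laird between-batch
    variance) and test the pooled effect by a Wald z.  A batch lacking a
    gene simply contributes no evidence for it; weights are renormalized
    over the batches that do.
    """
    if not per_batch:
        raise ValueError("need at least one per-batch result")
    config = config or MetaConfig()

    frames = []
    for k, res in enumerate(per_batch):
        df = pd.DataFrame(
            {
                "gene_id": res.gene_ids,
                "p": res.p_value,
                "sign": res.sign,
                "logfc": res.logfc,
                "se": res.se if res.se is not None else np.nan,
                "batch_idx": k,
                "n": res.n_genes_tested,
            }
        )
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    genes = pd.unique(long["gene_id"])

    batch_w = config.weight_vector(len(per_batch))

    p_comb = np.ones(len(genes))
    sign_comb = np.zeros(len(genes), dtype=int)
    logfc_comb = np.zeros(len(genes))

    grouped = long.groupby("gene_id", sort=False)
    for gi, gene in enumerate(genes):
        sub = grouped.get_group(gene)
        idx = sub["batch_idx"].to_numpy()
        w = batch_w[idx]
        p = sub["p"].to_numpy()
        sgn = sub["sign"].to_numpy()
        lfc = sub["logfc"].to_numpy()
        if config.combiner == "weighted_fisher":
            p_right = _weighted_fisher(_one_sided(p, sgn, +1), w)
            p_left = _weighted_fisher(_one_sided(p, sgn, -1), w)
            smaller = min(p_right, p_left)
            p_comb[gi] = min(1.0, 2.0 * smaller)
            if p_right < p_left:
                sign_comb[gi] = 1
            elif p_left < p_right:
                sign_comb[gi] = -1
            finite = np.isfinite(lfc)
            logfc_comb[gi] = (
                np.average(lfc[finite], weights=w[finite]) if finite.any() else np.nan
            )
        else:
            se = sub["se"].to_numpy()
            ok = np.isfinite(lfc) & np.isfinite(se) & (se > 0)
            if not ok.any():
                p_comb[gi] = 1.0
                continue
            theta, s = lfc[ok], se[ok]
            iv = 1.0 / s**2
            pooled = float(np.sum(iv * theta) / np.sum(iv))
            if config.combiner == "random_effects" and ok.sum() > 1:
                q = float(np.sum(iv * (theta - pooled) ** 2))
                c = float(np.sum(iv) - np.sum(iv**2) / np.sum(iv))
                tau2 = max(0.0, (q - (ok.sum() - 1)) / c) if c > 0 else 0.0
                iv = 1.0 / (s**2 + tau2)
                pooled = float(np.sum(iv * theta) / np.sum(iv))
            se_pooled = float(1.0 / np.sqrt(np.sum(iv)))
            z = pooled / se_pooled
            p_comb[gi] = 2.0 * scipy.stats.norm.sf(abs(z))
            logfc_comb[gi] = pooled
            sign_comb[gi] = int(np.sign(pooled))

    return DEResult(
        gene_ids=genes,
        p_value=p_comb,
        q_value=bh_adjust(p_comb),
        logfc=logfc_comb,
        sign=sign_comb,
        method=f"meta_{config.combiner}",
    )


def meta_de(
    counts: CountMatrix,
    config: MetaConfig | None = None,
    max_zero_rate: float = 0.95,
) -> DEResult:
    """Per-batch DE followed by meta-combination.

    Each batch is re-filtered (zero rate > ``max_zero_rate``) and
    log-normalized independently before the within-batch engine runs, so a
    gene too sparse in one batch contributes no evidence from it.
    """
    config = config or MetaConfig()
    engines = {"wilcoxon": wilcoxon_de, "lognorm_ttest": lognorm_ttest_de}
    if config.engine not in engines:
        raise ValueError(f"unknown engine {config.engine!r}")
    if config.combiner in ("fixed_effects", "random_effects") and config.engine == "wilcoxon":
        raise ValueError("effect-size combiners require an engine with standard errors")
    per_batch = []
    sizes = {}
    for b in counts.batches:
        sub = counts.subset_cells(counts.batch == b)
        sub = filter_genes(sub, max_zero_rate=max_zero_rate)
        res = engines[config.engine](log_normalize(sub))
        per_batch.append(res)
        sizes[b] = int(sub.n_cells)
    cfg = MetaConfig(
        combiner=config.combiner,
        weights=config.weights or sizes,
        engine=config.engine,
    )
    return meta_combine(per_batch, cfg)


def read_external_result(path) -> DEResult:
    """Load an externally computed DE result from the common TSV schema.

    Requires columns ``gene_id``, ``logfc``, ``pvalue``; ``qvalue`` and
    ``sign`` are optional (q-values are recomputed by BH when absent, signs
    default to the sign of logfc).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "logfc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external result missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df["gene_id"][df["gene_id"].duplicated()].head().tolist()
        raise ValueError(f"duplicate gene ids in external result: {dupes}")
    p = df["pvalue"].to_numpy(dtype=float)
    bad = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    if bad.size:
        raise ValueError(f"p-value outside [0, 1] at row {bad[0] + 2} of {path}")
    logfc = df["logfc"].to_numpy(dtype=float)
    sign = (
        df["sign"].to_numpy(dtype=int)
        if "sign" in df.columns
        else _signs_from_logfc(logfc)
    )
    q = df["qvalue"].to_numpy(dtype=float) if "qvalue" in df.columns else bh_adjust(p)
    method = str(df["method"].iloc[0]) if "method" in df.columns else "external"
    return DEResult(
        gene_ids=df["gene_id"].to_numpy(dtype=object),
        p_value=p,
        q_value=q,
        logfc=logfc,
        sign=sign,
        method=method,
    )
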