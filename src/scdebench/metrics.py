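"""Evaluation statistics for DE workflows.

Detection accuracy against simulated truth is summarised by the
precision-weighted F-beta score and the partial area under the
precision-recall curve (pAUPR, recall < T).  Direction fidelity is the
error ratio (percent of DE genes whose declared sign contradicts truth)
and, for batch-corrected data, the angular distortion of logFC values from
the identity line.  Rank-based detection of weighted standard-positive
genes (e.g. disease genes with association scores) uses the cumulative
score curve, its partial area over the top rank fraction (pAUC), and a
truncated weighted one-sided Kolmogorov-Smirnov test whose maximum
discrepancy is confined to the top ranks by a linear bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import (
    STATUS_DOWN,
    STATUS_UP,
    DEResult,
    SimTruth,
    WeightedGeneSet,
)
from .de_methods import signed_score

__all__ = [
    "MetricConfig",
    "f_beta",
    "rank_genes",
    "PRCurve",
    "pr_curve",
    "paupr",
    "error_ratio",
    "DistortionResult",
    "distortion",
    "cumulative_score_curve",
    "pauc",
    "KSResult",
    "truncated_ks_test",
    "FalseCallCounts",
    "count_false_calls",
    "rank_similarity",
    "evaluate_workflow",
]

_DIRECTION_SIGN = {STATUS_UP: 1, STATUS_DOWN: -1}


@dataclass
class MetricConfig:
    """Knobs shared by the evaluation statistics (defaults as benchmarked:
    beta = 0.5 weighing precision twice, pAUPR truncation T = 0.5,
    significance q < 0.05, top 20% ranks for pAUC / truncated KS)."""

    f_beta: float = 0.5
    paupr_T: float = 0.5
    q_threshold: float = 0.05
    top_fraction: float = 0.2
    n_permutations: int = 10_000
    logfc_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.f_beta <= 0:
            raise ValueError("f_beta must be positive")
        if not 0.0 < self.paupr_T <= 1.0:
            raise ValueError("paupr_T must lie in (0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be nonnegative")


def f_beta(precision: float, recall: float, beta: float = 0.5) -> float:
    """Generalized F-score ``(1+b^2) P R / (b^2 P + R)``; 0 when P = R = 0.

    ``beta < 1`` weighs precision higher than recall.
    """
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1.0 + beta**2) * precision * recall / denom


def rank_genes(result: DEResult) -> np.ndarray:
    """Indices sorting genes by significance.

    Order: p-value ascending; ties broken by larger absolute signed score,
    then lexicographic gene id.  Every rank-based metric in this module
    shares this rule.
    """
    score = np.abs(signed_score(result))
    gene_key = result.gene_ids.astype(str)
    return np.lexsort((gene_key, -score, result.p_value))


@dataclass
class PRCurve:
    """Per-rank precision/recall along the significance ordering."""

    recall: np.ndarray
    precision: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    point_at_q: tuple | None  # (recall, precision) at the q-threshold cut
    n_positives: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.p_value,
                "recall": self.recall,
                "precision": self.precision,
                "q": self.q_value,
            }
        )


def pr_curve(
    result: DEResult,
    truth: SimTruth,
    direction: str,
    q_threshold: float = 0.05,
) -> PRCurve:
    """Precision-recall curve for one DE direction.

    All genes are ranked by p-value; a gene counts as a true positive only
    if it is simulated DE in ``direction`` *and* the workflow declared the
    matching sign.
    """
    truth = truth.subset(result.gene_ids)
    positive = truth.direction_mask(direction)
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError(f"truth contains no {direction!r} gene")
    want_sign = _DIRECTION_SIGN[direction]

    order = rank_genes(result)
    is_tp = (positive & (result.sign == want_sign))[order]
    tp = np.cumsum(is_tp)
    ranks = np.arange(1, len(order) + 1)
    recall = tp / n_pos
    precision = tp / ranks
    q_sorted = result.q_value[order]

    point = None
    sig = np.flatnonzero(q_sorted < q_threshold)
    if sig.size:
        k = sig[-1]
        point = (float(recall[k]), float(precision[k]))
    return PRCurve(
        recall=recall,
        precision=precision,
        p_value=result.p_value[order],
        q_value=q_sorted,
        point_at_q=point,
        n_positives=n_pos,
    )


def paupr(curve: PRCurve, T: float = 0.5) -> float:
    """Partial AUPR: ``(1/T) * integral_0^T precision d(recall)``.

    Precision is integrated as a right-continuous step function of recall:
    each increment of recall contributes at the precision attained when
    that recall is first reached.
    """
    if not 0.0 < T <= 1.0:
        raise ValueError("T must lie in (0, 1]")
    events = np.flatnonzero(np.diff(np.concatenate([[0.0], curve.recall])) > 0)
    area = 0.0
    prev_r = 0.0
    for k in events:
        r = min(curve.recall[k], T)
        area += curve.precision[k] * (r - min(prev_r, T))
        prev_r = curve.recall[k]
        if prev_r >= T:
            break
    return area / T


def error_ratio(
    result: DEResult,
    truth: SimTruth,
    scope: str = "all_de",
    q_threshold: float = 0.05,
) -> float:
    """Percent of simulated DE genes whose declared sign contradicts truth.

    ``scope="detected"`` restricts to genes significant at
    ``q < q_threshold``.  Genes with non-finite logFC are excluded from
    numerator and denominator.  Returns NaN when the scope is empty.
    """
    if scope not in ("all_de", "detected"):
        raise ValueError("scope must be 'all_de' or 'detected'")
    truth = truth.subset(result.gene_ids)
    in_scope = truth.de_mask() & np.isfinite(result.logfc)
    if scope == "detected":
        in_scope &= result.q_value < q_threshold
    n = int(in_scope.sum())
    if n == 0:
        return float("nan")
    expected = np.where(truth.status == STATUS_UP, 1, -1)
    wrong = int((result.sign[in_scope] != expected[in_scope]).sum())
    return 100.0 * wrong / n


@dataclass
class DistortionResult:
    value: float
    n_used: int
    n_dropped: int


def distortion(
    logfc_raw: pd.DataFrame,
    logfc_corrected: pd.DataFrame,
    de_genes: np.ndarray,
) -> DistortionResult:
    """Mean angular (cosine) distance of (raw, corrected) logFC pairs from y = x.

    Per gene: ``1 - sign(lfc_raw) * <(1,1), (lfc_raw, lfc_corr)> /
    (sqrt(2) * ||(lfc_raw, lfc_corr)||)``.  Genes with non-finite logFC in
    either table, or with both logFCs exactly zero, are dropped and
    counted.  A faithful correction (corrected == raw) scores 0; a
    sign-inverting one scores 1 on average and the range is [0, 2].
    """
    raw = logfc_raw.set_index("gene_id")["logfc"]
    corr = logfc_corrected.set_index("gene_id")["logfc"]
    de_genes = list(de_genes)
    x = raw.reindex(de_genes).to_numpy(dtype=float)
    y = corr.reindex(de_genes).to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    norm = np.hypot(x, y)
    usable = finite & (norm > 0)
    n_dropped = int(len(de_genes) - usable.sum())
    if not usable.any():
        raise ValueError("no usable (finite, nonzero) logFC pair among DE genes")
    xs, ys, ns = x[usable], y[usable], norm[usable]
    terms = 1.0 - np.sign(xs) * (xs + ys) / (np.sqrt(2.0) * ns)
    return DistortionResult(
        value=float(terms.mean()), n_used=int(usable.sum()), n_dropped=n_dropped
    )


def cumulative_score_curve(
    result: DEResult, positives: WeightedGeneSet
) -> np.ndarray:
    """Running normalized sum of standard-positive weights along the ranking.

    ``curve[u-1]`` is the fraction of total positive weight captured within
    the top ``u`` ranks; it reaches 1 at the bottom of the ranking.
    """
    order = rank_genes(result)
    w = positives.weight_vector(result.gene_ids)[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("no overlap between positive gene set and ranked genes")
    return np.cumsum(w) / total


def pauc(curve: np.ndarray, top_fraction: float = 0.2) -> float:
    """Normalized area under the cumulative score curve over the top ranks.

    Averages the curve over ranks ``1..floor(top_fraction * u_max)``; a
    curve pinned at 1 throughout gives 1.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = int(np.floor(top_fraction * len(curve)))
    if n < 1:
        raise ValueError("top_fraction selects no rank")
    return float(np.mean(curve[:n]))


@dataclass
class KSResult:
    statistic: float
    p_value: float
    empirical_cdf: np.ndarray = field(repr=False)
    bridged_cdf: np.ndarray = field(repr=False)
    null_cdf: np.ndarray = field(repr=False)
    truncation_rank: int
    u_max: int


def _bridge(f_x: np.ndarray, n_trunc: int) -> np.ndarray:
    """Replace the empirical cdf beyond the truncation rank by the linear
    bridge from its value at the truncation rank to 1."""
    u_max = len(f_x)
    out = f_x.copy()
    if n_trunc < u_max:
        u = np.arange(n_trunc, u_max + 1)  # ranks N..u_max (1-based)
        out[n_trunc - 1 :] = f_x[n_trunc - 1] + (u - n_trunc) / (u_max - n_trunc) * (
            1.0 - f_x[n_trunc - 1]
        )
    return out


def _truncated_d_plus(w_sorted: np.ndarray, n_trunc: int) -> float:
    """Max of (bridged empirical cdf - uniform cdf); reduces to the top
    ranks because the bridge is linear and anchored at zero discrepancy."""
    u_max = len(w_sorted)
    f_x = np.cumsum(w_sorted[:n_trunc]) / w_sorted.sum()
    f_y = np.arange(1, n_trunc + 1) / u_max
    return float(max(0.0, np.max(f_x - f_y)))


def truncated_ks_test(
    result: DEResult,
    positives: WeightedGeneSet,
    top_fraction: float = 0.2,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> KSResult:
    """Truncated weighted one-sided KS test of positive-gene enrichment.

    The empirical cdf accumulates normalized positive weights along the
    p-value ranking; beyond the top ``top_fraction`` of ranks it is
    replaced by a linear bridge to 1, so the maximum discrepancy against
    the uniform null cdf can only arise within the top ranks.  The
    right-tailed p-value comes from permuting which ranks carry the weight
    multiset, with add-one correction ``(b + 1) / (m + 1)``.

    With ``top_fraction = 1`` the statistic is the classic weighted D+.
    """
    order = rank_genes(result)
    w = positives.weight_vector(result.gene_ids)[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero on the ranked genes")
    u_max = len(w)
    n_trunc = int(np.floor(top_fraction * u_max))
    if n_trunc < 1:
        raise ValueError("truncation rank below 1; increase top_fraction")

    observed = _truncated_d_plus(w, n_trunc)

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_permutations, int(2e6 // max(u_max, 1)) or 1))
    done = 0
    f_y_top = np.arange(1, n_trunc + 1) / u_max
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = rng.permuted(np.broadcast_to(w, (m, u_max)).copy(), axis=1)
        f_x = np.cumsum(perms[:, :n_trunc], axis=1) / total
        d = np.maximum(0.0, (f_x - f_y_top[None, :]).max(axis=1))
        exceed += int((d >= observed).sum())
        done += m
    p = (exceed + 1) / (n_permutations + 1)

    f_x_full = np.cumsum(w) / total
    return KSResult(
        statistic=observed,
        p_value=float(p),
        empirical_cdf=f_x_full,
        bridged_cdf=_bridge(f_x_full, n_trunc),
        null_cdf=np.arange(1, u_max + 1) / u_max,
        truncation_rank=n_trunc,
        u_max=u_max,
    )


@dataclass
class FalseCallCounts:
    n_p_lt_threshold: int
    n_q_lt_threshold: int
    reference_5pct: float


def count_false_calls(result: DEResult, threshold: float = 0.05) -> FalseCallCounts:
    """Counts of nominal (p) and FDR-adjusted (q) calls on a null design.

    On data with no injected DE signal these are false positives and false
    discoveries; the 5%-of-genes reference line is included for plotting.
    """
    return FalseCallCounts(
        n_p_lt_threshold=int((result.p_value < threshold).sum()),
        n_q_lt_threshold=int((result.q_value < threshold).sum()),
        reference_5pct=0.05 * result.n_genes_tested,
    )


def rank_similarity(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Spearman correlation of two signed-score vectors on their common genes."""
    common = scores_a.index.intersection(scores_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    rho, _ = scipy.stats.spearmanr(
        scores_a.loc[common].to_numpy(), scores_b.loc[common].to_numpy()
    )
    return float(rho)


def evaluate_workflow(
    result: DEResult,
    truth: SimTruth | None = None,
    geneset: WeightedGeneSet | None = None,
    config: MetricConfig | None = None,
    seed: int = 0,
) -> dict:
    """Compute the full metric report for one workflow.

    With simulated ``truth``: directional F-beta at the q-threshold,
    directional pAUPR, error ratios (all-DE and detected-only).  With a
    weighted ``geneset``: pAUC of the cumulative score curve and the
    truncated KS statistic/p-value.  False-call counts are always included
    (meaningful on null designs).
    """
    config = config or MetricConfig()
    report: dict = {"method": result.method, "n_genes": result.n_genes_tested}

    if truth is not None:
        truth_here = truth.subset(result.gene_ids)
        detected = result.q_value < config.q_threshold
        if config.logfc_threshold > 0:
            detected &= np.abs(result.logfc) > config.logfc_threshold
        for direction, want in ((STATUS_UP, 1), (STATUS_DOWN, -1)):
            pos = truth_here.direction_mask(direction)
            called = detected & (result.sign == want)
            tp = int((called & pos).sum())
            precision = tp / called.sum() if called.any() else 0.0
            recall = tp / pos.sum() if pos.any() else 0.0
            report[f"f_beta_{direction}"] = f_beta(precision, recall, config.f_beta)
            report[f"precision_{direction}"] = precision
            report[f"recall_{direction}"] = recall
            curve = pr_curve(result, truth_here, direction, config.q_threshold)
            report[f"paupr_{direction}"] = paupr(curve, config.paupr_T)
        report["error_ratio_all"] = error_ratio(
            result, truth_here, "all_de", config.q_threshold
        )
        report["error_ratio_detected"] = error_ratio(
            result, truth_here, "detected", config.q_threshold
        )

    if geneset is not None:
        curve = cumulative_score_curve(result, geneset)
        report["pauc"] = pauc(curve, config.top_fraction)
        ks = truncated_ks_test(
            result,
            geneset,
            top_fraction=config.top_fraction,
            n_permutations=config.n_permutations,
            seed=seed,
        )
        report["ks_statistic"] = ks.statistic
        report["ks_p_value"] = ks.p_value

    calls = count_false_calls(result)
    report["n_p_lt_05"] = calls.n_p_lt_threshold
    report["n_q_lt_05"] = calls.n_q_lt_threshold
    return report
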