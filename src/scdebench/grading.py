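"""Good/Intermediate/Poor classification of DE workflows and benchmark
orchestration.

Five performance axes are graded: standard-positive detection (truncated
KS p-value plus pAUC rank), false-positive/false-discovery control on null
designs, sign preservation (relative spread of error-ratio distributions),
speed (wall-clock on designated small/large fixtures) and scalability (the
proportionality coefficient of runtime against sqrt(cells x genes)).

All printed rules use strict inequalities on both sides, so exact boundary
values fall to Intermediate.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .containers import CountMatrix, DEResult, SimTruth, WeightedGeneSet
from .de_methods import (
    MetaConfig,
    covariate_glm_de,
    meta_de,
    pseudobulk_aggregate,
    pseudobulk_de,
    read_external_result,
    wilcoxon_de,
)
from .metrics import MetricConfig, evaluate_workflow
from .preprocess import filter_genes, log_normalize
from .sim_downsample import DownsampleParams, simulate_downsample
from .sim_splat import SplatParams, get_preset, simulate_counts

logger = logging.getLogger("scdebench")

GOOD = "Good"
INTERMEDIATE = "Intermediate"
POOR = "Poor"


def classify_detection(ks_p: float, pauc_rank: int) -> str:
    """Detection grade: Good iff KS p < 0.01 and pAUC rank <= 10; Poor iff
    p > 0.01 or rank > 20; otherwise Intermediate."""
    if ks_p is None or pauc_rank is None or not np.isfinite(ks_p):
        raise ValueError("both KS p-value and pAUC rank are required")
    if ks_p < 0.01 and pauc_rank <= 10:
        return GOOD
    if ks_p > 0.01 or pauc_rank > 20:
        return POOR
    return INTERMEDIATE


def classify_fp_fd(
    fp_counts: dict[str, list[int]],
    fd_counts: dict[str, list[int]],
    n_genes: int,
) -> str:
    """False-positive/false-discovery grade from repeated null-split runs.

    ``fp_counts`` / ``fd_counts`` map depth regime (two expected: low and
    moderate) to per-run counts.  Good requires zero median false
    discoveries and median false positives at most 5% of genes at *both*
    depths; Poor requires positive median false discoveries at both depths
    and median false positives above 5% at either.
    """
    regimes = sorted(fp_counts)
    if set(regimes) != set(fd_counts) or not regimes:
        raise ValueError("fp and fd counts must cover the same nonempty regimes")
    for r in regimes:
        if len(fp_counts[r]) == 0 or len(fd_counts[r]) == 0:
            raise ValueError(f"regime {r!r} has no runs")
    med_fp = {r: float(np.median(fp_counts[r])) for r in regimes}
    med_fd = {r: float(np.median(fd_counts[r])) for r in regimes}
    limit = 0.05 * n_genes
    if all(med_fd[r] == 0 for r in regimes) and all(
        med_fp[r] <= limit for r in regimes
    ):
        return GOOD
    if all(med_fd[r] > 0 for r in regimes) and any(med_fp[r] > limit for r in regimes):
        return POOR
    return INTERMEDIATE


def _tukey_whiskers(x: np.ndarray) -> tuple[float, float]:
    """Boxplot whisker ends: extreme data points within 1.5 IQR of the box."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return float(lo), float(hi)


def sign_preservation_P(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Relative median shift between two performance distributions.

    ``P = 100 * |median_a - median_b| / OVS`` where the overall visible
    spread (OVS) is the span from the lowest to the highest Tukey whisker
    across both samples.  Identical samples give 0; equal medians with
    zero spread give 0; unequal medians with zero spread are degenerate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    dbm = abs(float(np.median(a)) - float(np.median(b)))
    lo_a, hi_a = _tukey_whiskers(a)
    lo_b, hi_b = _tukey_whiskers(b)
    ovs = max(hi_a, hi_b) - min(lo_a, lo_b)
    if ovs == 0:
        if dbm == 0:
            return 0.0
        raise ValueError("degenerate: zero visible spread with unequal medians")
    return 100.0 * dbm / ovs


def classify_sign_preservation(P: float) -> str:
    if P < 30.0:
        return GOOD
    if P > 60.0:
        return POOR
    return INTERMEDIATE


def classify_speed(runtime_small: float, runtime_large: float) -> str:
    """Speed grade from runtimes (seconds) on the designated small and large
    benchmark fixtures: Good if large < 600 s; Poor if small > 1800 s or
    large > 10800 s."""
    if runtime_small is None or runtime_large is None:
        raise ValueError("both runtimes are required")
    if runtime_large < 600.0:
        return GOOD
    if runtime_small > 1800.0 or runtime_large > 10800.0:
        return POOR
    return INTERMEDIATE


@dataclass
class ScalabilityFit:
    """One-parameter least-squares fit ``T = alpha * sqrt(N * M)``."""

    alpha: float
    sizes: np.ndarray
    times: np.ndarray
    residuals: np.ndarray


def fit_scalability(
    times: np.ndarray, sizes: list[tuple[int, int]]
) -> ScalabilityFit:
    """Fit runtime against sqrt(cells x genes) through the origin.

    ``alpha = sum(T_i s_i) / sum(s_i^2)`` with ``s_i = sqrt(N_i M_i)``.
    """
    T = np.asarray(times, dtype=float)
    s = np.array([np.sqrt(n * m) for n, m in sizes], dtype=float)
    if T.size == 0 or T.size != s.size:
        raise ValueError("need matching, nonempty times and sizes")
    denom = float((s**2).sum())
    if denom == 0:
        raise ValueError("all sizes are zero")
    alpha = float((T * s).sum() / denom)
    return ScalabilityFit(alpha=alpha, sizes=s, times=T, residuals=T - alpha * s)


def classify_scalability(alpha: float) -> str:
    if alpha < 1.0:
        return GOOD
    if alpha > 2.0:
        return POOR
    return INTERMEDIATE


# ---------------------------------------------------------------------------
# Benchmark orchestration


_NATIVE_METHODS = {
    "wilcoxon",
    "glm",
    "glm-cov",
    "pseudobulk",
    "meta-wfisher",
    "meta-fem",
    "meta-rem",
}


def run_native_workflow(method: str, counts: CountMatrix) -> DEResult:
    """Dispatch one of the native DE workflows on a filtered count matrix."""
    if method == "wilcoxon":
        return wilcoxon_de(log_normalize(counts))
    if method == "glm":
        return covariate_glm_de(counts, include_batch=False)[0]
    if method == "glm-cov":
        return covariate_glm_de(counts, include_batch=True)[0]
    if method == "pseudobulk":
        return pseudobulk_de(pseudobulk_aggregate(counts))
    if method == "meta-wfisher":
        return meta_de(counts, MetaConfig(combiner="weighted_fisher"))
    if method == "meta-fem":
        return meta_de(counts, MetaConfig(combiner="fixed_effects"))
    if method == "meta-rem":
        return meta_de(counts, MetaConfig(combiner="random_effects"))
    raise ValueError(f"unknown native method {method!r}")


def _load_fixture(spec: dict, seed: int) -> tuple[CountMatrix, SimTruth | None]:
    kind = spec.get("kind", "splat")
    if kind == "splat":
        if "preset" in spec:
            params = get_preset(spec["preset"], seed=seed, **spec.get("params", {}))
        else:
            params = SplatParams(seed=seed, **spec.get("params", {}))
        return simulate_counts(params)
    if kind == "downsample":
        source = _io.read_count_matrix(spec["counts"])
        params = DownsampleParams(seed=seed, **spec.get("params", {}))
        return simulate_downsample(source, params)
    if kind == "files":
        cm = _io.read_count_matrix(spec["counts"])
        truth = _io.read_truth(spec["truth"]) if "truth" in spec else None
        return cm, truth
    raise ValueError(f"unknown fixture kind {kind!r}")


def run_benchmark(config: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute (or ingest) every declared workflow on every fixture.

    ``config`` sections: ``fixtures`` (list of simulator/file specs),
    ``workflows`` (native method names or external result paths),
    ``metrics`` (MetricConfig fields), optional ``geneset`` path, optional
    ``runtimes`` ({workflow: {small, large}} in seconds) and ``seed``.
    Returns a per-(fixture, workflow) metric table and a per-workflow
    grade table.  External result paths are validated before any
    computation starts.
    """
    seed = int(config.get("seed", 0))
    metric_cfg = MetricConfig(**config.get("metrics", {}))
    workflows = config.get("workflows", [])
    fixtures = config.get("fixtures", [])
    if not workflows or not fixtures:
        raise ValueError("config must declare at least one fixture and workflow")

    for wf in workflows:
        if "path" in wf:
            if not Path(wf["path"]).exists():
                raise FileNotFoundError(
                    f"external result for workflow {wf['name']!r} not found: {wf['path']}"
                )
        elif wf.get("method") not in _NATIVE_METHODS:
            raise ValueError(f"workflow {wf['name']!r}: unknown method")

    geneset = _io.read_geneset(config["geneset"]) if "geneset" in config else None

    rows = []
    for fi, fx in enumerate(fixtures):
        fixture_name = fx.get("name", f"fixture{fi}")
        logger.info("preparing fixture %s", fixture_name)
        counts, truth = _load_fixture(fx, seed + fi)
        counts = filter_genes(counts)
        if truth is not None:
            truth = truth.subset(counts.gene_ids)
        for wf in workflows:
            t0 = time.perf_counter()
            if "path" in wf:
                result = read_external_result(wf["path"])
            else:
                result = run_native_workflow(wf["method"], counts)
            elapsed = time.perf_counter() - t0
            report = evaluate_workflow(
                result, truth=truth, geneset=geneset, config=metric_cfg, seed=seed
            )
            report.update(
                {
                    "workflow": wf["name"],
                    "fixture": fixture_name,
                    "runtime_s": elapsed,
                }
            )
            rows.append(report)
            logger.info(
                "workflow %s on %s done in %.2fs", wf["name"], fixture_name, elapsed
            )
    metrics_df = pd.DataFrame(rows)

    grade_rows = []
    runtimes = config.get("runtimes", {})
    for wf in workflows:
        name = wf["name"]
        sub = metrics_df[metrics_df["workflow"] == name]
        grade: dict = {"workflow": name}
        if geneset is not None and "pauc" in metrics_df.columns:
            by_fixture = []
            for fixture_name, fsub in metrics_df.groupby("fixture"):
                ranked = fsub.sort_values("pauc", ascending=False)
                rank = int(np.flatnonzero(ranked["workflow"].to_numpy() == name)[0]) + 1
                row = fsub[fsub["workflow"] == name].iloc[0]
                by_fixture.append(classify_detection(row["ks_p_value"], rank))
            order = {GOOD: 0, INTERMEDIATE: 1, POOR: 2}
            grade["detection"] = max(by_fixture, key=lambda c: order[c])
            grade["ks_p_value"] = float(sub["ks_p_value"].median())
            grade["pauc"] = float(sub["pauc"].median())
        if name in runtimes:
            rt = runtimes[name]
            grade["speed"] = classify_speed(rt.get("small"), rt.get("large"))
        grade_rows.append(grade)
    grades_df = pd.DataFrame(grade_rows)
    return metrics_df, grades_df


def write_provenance(path: str | Path, config: dict, extra: dict | None = None) -> None:
    record = {
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
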