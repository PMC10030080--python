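"""Principal variance component analysis (PVCA).

Quantifies the fractions of expression variance attributable to batch,
group, their interaction, and residual noise.  The data are reduced by PCA
(retaining components until a cumulative variance threshold), each
principal component's scores are decomposed by a two-random-factor model
with interaction (expected-mean-squares ANOVA by default, REML available),
and per-factor components are averaged across components weighted by each
component's share of variance.

Used here to label simulation scenarios as small vs large batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = ["PVCAResult", "pvca"]

FACTORS = ("batch", "group", "batch_x_group", "residual")


@dataclass
class PVCAResult:
    """Variance proportions per factor (nonnegative, summing to 1)."""

    proportions: dict[str, float]
    n_pcs: int
    var_threshold: float

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("variance proportions must sum to 1")


def _reml_components(
    y: np.ndarray, batch: np.ndarray, group: np.ndarray
) -> dict[str, float]:
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "batch": batch, "group": group, "one": 1})
    vcf = {
        "batch": "0 + C(batch)",
        "group": "0 + C(group)",
        "batch_x_group": "0 + C(batch):C(group)",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "y ~ 1", data=df, groups="one", vc_formula=vcf, re_formula="0"
        )
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not np.all(np.isfinite(fit.vcomp)):
        raise RuntimeError("REML produced non-finite variance components")
    names = model.exog_vc.names
    comp = {name: max(0.0, float(v)) for name, v in zip(names, fit.vcomp)}
    comp["residual"] = max(0.0, float(fit.scale))
    return {f: comp.get(f, 0.0) for f in FACTORS}


def _moments_components(
    y: np.ndarray, batch: np.ndarray, group: np.ndarray
) -> dict[str, float]:
    """ANOVA method-of-moments fallback (expected mean squares with the
    average cell count standing in for the balanced-design replicate
    number; negative estimates truncated at zero)."""
    df = pd.DataFrame({"y": y, "batch": batch, "group": group})
    cell_means = df.groupby(["batch", "group"], observed=True)["y"].agg(
        ["mean", "count"]
    )
    n_bar = float(cell_means["count"].mean())
    mse = float(
        df.groupby(["batch", "group"], observed=True)["y"]
        .var(ddof=1)
        .fillna(0.0)
        .mean()
    )
    grand = float(df["y"].mean())
    batch_means = df.groupby("batch", observed=True)["y"].mean()
    group_means = df.groupby("group", observed=True)["y"].mean()
    b_levels, g_levels = len(batch_means), len(group_means)
    interaction = cell_means["mean"].copy()
    for (b, g), _ in interaction.items():
        interaction.loc[(b, g)] -= batch_means[b] + group_means[g] - grand
    ms_int = (
        float((interaction**2).sum()) / max((b_levels - 1) * (g_levels - 1), 1) * n_bar
    )
    ms_batch = float(((batch_means - grand) ** 2).sum()) / max(b_levels - 1, 1) * (
        n_bar * g_levels
    )
    ms_group = float(((group_means - grand) ** 2).sum()) / max(g_levels - 1, 1) * (
        n_bar * b_levels
    )
    var_int = max(0.0, (ms_int - mse) / n_bar)
    var_batch = max(0.0, (ms_batch - ms_int) / (n_bar * g_levels))
    var_group = max(0.0, (ms_group - ms_int) / (n_bar * b_levels))
    return {
        "batch": var_batch,
        "group": var_group,
        "batch_x_group": var_int,
        "residual": max(mse, 1e-12),
    }


def pvca(
    norm: NormalizedMatrix,
    batch: np.ndarray | None = None,
    group: np.ndarray | None = None,
    var_threshold: float = 0.6,
    max_pcs: int = 20,
    subsample: int | None = None,
    seed: int = 0,
    estimator: str = "moments",
) -> PVCAResult:
    """Partition expression variance over batch, group, interaction, residual.

    PCA runs on cells x genes (gene-centered); components are retained
    until their cumulative explained variance reaches ``var_threshold``
    (capped at ``max_pcs``).  Each retained component's scores are
    decomposed into the four variance components, and the per-factor
    results are averaged across components weighted by explained variance.
    ``subsample`` draws a random subset of cells first, which makes the
    analysis tractable for large data at little cost in accuracy.

    ``estimator`` selects the per-component decomposition: the default
    ``"moments"`` (expected-mean-squares ANOVA, negative components
    truncated at zero) attributes a pure batch shift entirely to the batch
    factor; ``"reml"`` fits the two-random-factor mixed model by REML
    (falling back to moments on failure), but its likelihood is flat along
    the batch-versus-interaction direction when factor levels are few, so
    moment estimation is the default.
    """
    if estimator not in ("moments", "reml"):
        raise ValueError("estimator must be 'moments' or 'reml'")
    batch = norm.batch if batch is None else np.asarray(batch, dtype=object)
    group = norm.group if group is None else np.asarray(group, dtype=object)
    X = norm.values.T.astype(float)  # cells x genes
    n_cells = X.shape[0]
    if n_cells < 10:
        raise ValueError("need at least 10 cells")
    if len(pd.unique(batch)) < 2 or len(pd.unique(group)) < 2:
        raise ValueError("batch and group must each have at least 2 levels")

    if subsample is not None and subsample < n_cells:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n_cells, size=subsample, replace=False)
        X, batch, group = X[keep], batch[keep], group[keep]
        n_cells = subsample

    max_pcs = min(max_pcs, n_cells - 1, X.shape[1])
    if max_pcs < 1:
        raise ValueError("fewer cells than requested principal components")

    from sklearn.decomposition import PCA

    pca = PCA(n_components=max_pcs, random_state=seed)
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    evr = pca.explained_variance_ratio_
    n_pcs = int(np.searchsorted(np.cumsum(evr), var_threshold) + 1)
    n_pcs = min(max(n_pcs, 1), max_pcs)

    weights = evr[:n_pcs] / evr[:n_pcs].sum()
    acc = {f: 0.0 for f in FACTORS}
    for j in range(n_pcs):
        y = scores[:, j]
        if estimator == "reml":
            try:
                comp = _reml_components(y, batch, group)
            except Exception:
                comp = _moments_components(y, batch, group)
        else:
            comp = _moments_components(y, batch, group)
        total = sum(comp.values())
        if total <= 0:
            comp = {f: (1.0 if f == "residual" else 0.0) for f in FACTORS}
            total = 1.0
        for f in FACTORS:
            acc[f] += weights[j] * comp[f] / total

    total = sum(acc.values())
    proportions = {f: acc[f] / total for f in FACTORS}
    return PVCAResult(
        proportions=proportions, n_pcs=n_pcs, var_threshold=var_threshold
    )
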