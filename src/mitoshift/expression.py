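"""Heteroplasmy–expression association in single cells.

Two analyses on a cells × genes matrix: (1) partitioning per-gene expression
variance into cell stage, experimental batch, line identity, the mean
nonsynonymous mtDNA heteroplasmy fraction and residual noise; (2)
differential expression between mtDNA-genotype-defined sub-clones of one
line, with cell stage as covariate and Benjamini–Hochberg control.

The decomposition is an ordinary-least-squares one: each factor's share is
the variance of its fitted component over the total variance, which for a
single continuous predictor reduces to the familiar R² =
β²·Var(x) / (β²·Var(x) + σ²).  mtDNA-encoded and ribosomal genes should be
excluded by the caller (flags travel in the gene annotation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CARRIER_THRESHOLD = 0.02


def _log_normalise(expr: pd.DataFrame) -> pd.DataFrame:
    """log1p of counts-per-10k; a no-op for already-log data is acceptable."""
    totals = expr.sum(axis=1).replace(0, 1)
    return np.log1p(expr.div(totals, axis=0) * 1e4)


def select_variable_genes(expr: pd.DataFrame, n: int = 4000) -> list[str]:
    """Top-n genes ranked by overdispersion significance.

    A quadratic mean–variance trend is fitted in log space; genes are ranked
    by their standardised positive deviation from the trend.  Deterministic.
    """
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    keep = mean > 0
    log_mean = np.log1p(mean[keep])
    log_var = np.log1p(var[keep])
    coef = np.polyfit(log_mean, log_var, deg=2)
    resid = log_var - np.polyval(coef, log_mean)
    score = resid / max(resid.std(), 1e-12)
    ranked = score.sort_values(ascending=False).index.tolist()
    if n >= len(ranked):
        return ranked
    return ranked[:n]


def variance_components(expr: pd.DataFrame, meta: pd.DataFrame,
                        mean_nonsyn_hf: pd.Series | None = None,
                        factors: tuple = ("stage", "batch", "line_id"),
                        ) -> pd.DataFrame:
    """Per-gene variance fractions for stage / batch / line / mtDNA HF.

    Categorical factors enter as dummy blocks; ``mean_nonsyn_hf`` (indexed
    by cell) as a continuous predictor.  Fractions are Var(component) /
    Var(y) from a joint OLS fit; ``residual`` is 1 − R².  Single-level
    factors are dropped.  For the within-line analysis pass only the HF
    term (``factors=()``).
    """
    meta = meta.set_index("cell_id").loc[expr.index]
    blocks: dict[str, np.ndarray] = {}
    for f in factors:
        if f in meta.columns and meta[f].nunique() > 1:
            blocks[f] = pd.get_dummies(meta[f], drop_first=True).to_numpy(float)
    if mean_nonsyn_hf is not None:
        hf = mean_nonsyn_hf.reindex(expr.index).fillna(0.0)
        if hf.nunique() > 1:
            blocks["mtdna_hf"] = hf.to_numpy(float)[:, None]
    if not blocks:
        raise ValueError("no usable factors")
    X_parts = [np.ones((len(expr), 1))]
    spans = {}
    col = 1
    for name, b in blocks.items():
        spans[name] = (col, col + b.shape[1])
        X_parts.append(b)
        col += b.shape[1]
    X = np.column_stack(X_parts)
    Y = expr.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    total_var = Y.var(axis=0)
    total_var[total_var == 0] = np.nan
    out = {}
    for name, (a, b) in spans.items():
        comp = X[:, a:b] @ beta[a:b]
        out[name] = comp.var(axis=0) / total_var
    resid = Y - fitted
    out["residual"] = resid.var(axis=0) / total_var
    return pd.DataFrame(out, index=expr.columns)


def genotype_groups(hf: pd.Series, near_homoplasmic: float = 0.95,
                    split: float = 0.5) -> pd.Series:
    """Dichotomise per-cell HF of one variant into carrier / non-carrier.

    Default split is carrier = HF ≥ 2 %; when carriers are near-homoplasmic
    on average the split moves to HF ≥ 50 % so both groups are populated.
    """
    carrier = hf >= CARRIER_THRESHOLD
    if carrier.any() and hf[carrier].median() > near_homoplasmic:
        carrier = hf >= split
    return carrier.map({True: "carrier", False: "non_carrier"})


def de_by_mtdna_genotype(expr: pd.DataFrame, meta: pd.DataFrame,
                         genotype: pd.Series, *, min_cells_per_group: int = 15,
                         fdr: float = 0.1, exclude_genes=()) -> pd.DataFrame:
    """Differential expression between mtDNA genotype groups of one line.

    Log-linear OLS per gene: log-normalised expression ~ genotype + stage;
    the genotype coefficient's t-test p-values are BH-adjusted.  Requires at
    least ``min_cells_per_group`` cells in each genotype group.
    """
    genotype = genotype.reindex(expr.index)
    groups = genotype.value_counts()
    if len(groups) < 2:
        raise ValueError(
            f"only one genotype group present ({groups.index.tolist()})")
    if groups.min() < min_cells_per_group:
        raise ValueError("fewer than "
                         f"{min_cells_per_group} cells in a genotype group")
    keep = [g for g in expr.columns if g not in set(exclude_genes)]
    logged = _log_normalise(expr[keep])
    meta = meta.set_index("cell_id").reindex(expr.index)
    design = [np.ones(len(expr)), (genotype == "carrier").to_numpy(float)]
    names = ["intercept", "genotype"]
    if "stage" in meta.columns and meta["stage"].nunique() > 1:
        dummies = pd.get_dummies(meta["stage"], drop_first=True)
        for c in dummies.columns:
            design.append(dummies[c].to_numpy(float))
            names.append(f"stage_{c}")
    X = np.column_stack(design)
    Y = logged.to_numpy(float)
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    tvals = beta[1] / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({"gene": keep, "effect": beta[1], "se": se,
                        "p": pvals, "q": qvals,
                        "significant": qvals < fdr}).set_index("gene")
    return out
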