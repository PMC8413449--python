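"""Single-cell mtDNA heteroplasmy: stages, pseudo-bulk, lineage tracing.

Cells carry a cells × variants matrix of heteroplasmy fractions.  Stages
(iPSC / mesendo / defendo / undefined) are assigned from collection day and
pseudotime; pseudo-bulk HF is the zero-inclusive mean over cells of a line;
carrier statistics split that mean into carrier proportion × carrier-mean
HF; clonal lineages are recovered by hierarchical clustering of the HF
matrix (with an optional 2-D embedding for display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .reference import MT_LENGTH

CARRIER_THRESHOLD = 0.02  # single-cell carrier = HF >= 2 %, the bulk limit


def assign_stage(meta: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``stage`` column from collection day and pseudotime.

    mesendo: day 1 or 2 with pseudotime in [0.15, 0.5); defendo: day 2 or 3
    with pseudotime > 0.7; pseudotime in [0.5, 0.7] is undefined; day-0
    cells below 0.15 are iPSC.  Boundary values fall to the lower-labelled
    category.  Missing pseudotime yields undefined.
    """
    meta = meta.copy()

    def rule(row):
        day, pt = row["collection_day"], row["pseudotime"]
        if pd.isna(pt):
            return "undefined"
        if day in (1, 2) and 0.15 <= pt < 0.5:
            return "mesendo"
        if day in (2, 3) and pt > 0.7:
            return "defendo"
        if 0.5 <= pt <= 0.7:
            return "undefined"
        if day == 0 or pt < 0.15:
            return "iPSC"
        return "undefined"

    meta["stage"] = meta.apply(rule, axis=1)
    return meta


def pseudo_bulk_hf(matrix: pd.DataFrame, group: list | None = None) -> pd.Series:
    """Per-variant mean HF over all cells of the group, zeros included."""
    sub = matrix if group is None else matrix.loc[group]
    if len(sub) == 0:
        raise ValueError("empty cell group")
    return sub.mean(axis=0)


def carrier_statistics(matrix: pd.DataFrame, group: list | None = None,
                       threshold: float = CARRIER_THRESHOLD) -> pd.DataFrame:
    """Per-variant carrier proportion and mean HF among carriers.

    A carrier is a cell with HF ≥ 2 %.  With non-carriers at exactly zero,
    pseudo-bulk HF = proportion × carrier mean.
    """
    sub = matrix if group is None else matrix.loc[group]
    if len(sub) == 0:
        raise ValueError("empty cell group")
    carrier = sub >= threshold
    prop = carrier.mean(axis=0)
    mean_hf = sub.where(carrier).mean(axis=0)  # NaN when no carriers
    return pd.DataFrame({"carrier_proportion": prop,
                         "mean_carrier_hf": mean_hf})


def binned_mutation_frequency(matrix: pd.DataFrame,
                              bins=(0.0, 0.1, 0.25, 0.5, 0.75, 1.0),
                              threshold: float = CARRIER_THRESHOLD,
                              ) -> pd.DataFrame:
    """Mutation rate per bin of carrier proportion.

    rate = number of variants whose carrier proportion falls in the bin /
    (number of cells × 16,569 bp).  Bins partition (0, 1]; variants carried
    by no cell are excluded.
    """
    stats_df = carrier_statistics(matrix, threshold=threshold)
    prop = stats_df["carrier_proportion"]
    prop = prop[prop > 0]
    n_cells = len(matrix)
    edges = np.asarray(bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = int(((prop > lo) & (prop <= hi)).sum())
        rows.append({"bin_low": lo, "bin_high": hi, "n_variants": n,
                     "rate": n / (n_cells * MT_LENGTH)})
    return pd.DataFrame(rows)


def stage_concordance(matrix: pd.DataFrame, meta: pd.DataFrame,
                      min_cells_per_stage: int = 20,
                      threshold: float = CARRIER_THRESHOLD) -> pd.DataFrame:
    """Cross-stage concordance of per-variant carrier statistics, per line.

    For every line with ≥ 20 cells in each of two stages, correlates the
    log2 carrier proportions (variants carried in both stages) and the mean
    carrier HFs between the stages; returns Pearson R² and p per pair.
    Lines failing the cell-count rule are listed with ``included = False``.
    """
    rows = []
    for line, line_meta in meta.groupby("line_id"):
        stage_cells = {s: list(g["cell_id"])
                       for s, g in line_meta.groupby("stage")
                       if s != "undefined"}
        stages = sorted(stage_cells)
        for i, s1 in enumerate(stages):
            for s2 in stages[i + 1:]:
                ok = (len(stage_cells[s1]) >= min_cells_per_stage
                      and len(stage_cells[s2]) >= min_cells_per_stage)
                row = {"line_id": line, "stage_a": s1, "stage_b": s2,
                       "included": ok, "n_shared_variants": 0,
                       "r2_log2_proportion": np.nan, "p_proportion": np.nan,
                       "r2_mean_hf": np.nan}
                if ok:
                    ca = carrier_statistics(matrix, stage_cells[s1], threshold)
                    cb = carrier_statistics(matrix, stage_cells[s2], threshold)
                    both = (ca["carrier_proportion"] > 0) & (cb["carrier_proportion"] > 0)
                    row["n_shared_variants"] = int(both.sum())
                    if both.sum() >= 2:
                        x = np.log2(ca.loc[both, "carrier_proportion"])
                        y = np.log2(cb.loc[both, "carrier_proportion"])
                        if x.std() > 0 and y.std() > 0:
                            r, p = stats.pearsonr(x, y)
                            row["r2_log2_proportion"] = r * r
                            row["p_proportion"] = p
                        hx = ca.loc[both, "mean_carrier_hf"]
                        hy = cb.loc[both, "mean_carrier_hf"]
                        if hx.std() > 0 and hy.std() > 0:
                            r, _ = stats.pearsonr(hx, hy)
                            row["r2_mean_hf"] = r * r
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LineageResult:
    embedding: pd.DataFrame | None  # cells × 2, or None when not computed
    clusters: pd.Series             # cluster label per cell
    markers: pd.DataFrame           # per-cluster top marker variants
    n_variants_used: int
    note: str = ""
    embedding_params: dict | None = None


def lineage_clusters(matrix: pd.DataFrame, *,
                     min_carrier_fraction: float = 0.01,
                     distance_threshold: float | None = 2.0,
                     n_clusters: int | None = None,
                     embedding: str = "umap", seed: int = 0,
                     n_markers: int = 3) -> LineageResult:
    """mtDNA-based clonal lineages within one cell line.

    Variant columns carried by ≤ ``min_carrier_fraction`` of cells are
    dropped (the 1 %-carrier rule); cells are clustered by Ward
    agglomerative clustering on the HF matrix with a configurable dendrogram
    cut; markers are the variants whose cluster-mean HF deviates most from
    the other clusters.  ``embedding`` ∈ {'umap', 'pca', 'none'} controls
    the 2-D display coordinates (UMAP with a fixed seed by default).
    """
    carrier_frac = (matrix >= CARRIER_THRESHOLD).mean(axis=0)
    used = matrix.loc[:, carrier_frac > min_carrier_fraction]
    note = ""
    if used.shape[1] == 0:
        clusters = pd.Series(0, index=matrix.index, name="cluster")
        return LineageResult(None, clusters, pd.DataFrame(), 0,
                             note="no variants pass the carrier filter; "
                                  "single cluster returned")
    X = used.to_numpy(dtype=float)
    if n_clusters is None and len(used) > 1:
        model = AgglomerativeClustering(n_clusters=None, linkage="ward",
                                        distance_threshold=distance_threshold)
    else:
        model = AgglomerativeClustering(n_clusters=n_clusters or 1,
                                        linkage="ward")
    labels = (model.fit_predict(X) if len(used) > 1
              else np.zeros(len(used), dtype=int))
    clusters = pd.Series(labels, index=used.index, name="cluster")

    emb = None
    emb_params = None
    if embedding == "umap" and len(used) > 4:
        import umap

        n_neighbors = min(15, len(used) - 1)
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed)
        coords = reducer.fit_transform(X)
        emb = pd.DataFrame(coords, index=used.index, columns=["umap1", "umap2"])
        emb_params = {"method": "umap", "n_neighbors": n_neighbors,
                      "metric": "euclidean", "random_state": seed}
    elif embedding == "pca" or (embedding == "umap" and len(used) > 1):
        k = min(2, len(used) - 1, used.shape[1])
        if k >= 1:
            coords = PCA(n_components=k, random_state=seed).fit_transform(X)
            if k == 1:
                coords = np.column_stack([coords, np.zeros(len(coords))])
            emb = pd.DataFrame(coords, index=used.index,
                               columns=["pc1", "pc2"])
            emb_params = {"method": "pca", "random_state": seed}

    marker_rows = []
    overall = used.mean(axis=0)
    for cl in sorted(clusters.unique()):
        in_cl = used.loc[clusters == cl]
        delta = (in_cl.mean(axis=0) - overall).sort_values(ascending=False)
        for v in delta.index[:n_markers]:
            marker_rows.append({"cluster": cl, "variant": v,
                                "mean_hf_in_cluster": float(in_cl[v].mean()),
                                "mean_hf_overall": float(overall[v])})
    return LineageResult(emb, clusters, pd.DataFrame(marker_rows),
                         n_variants_used=used.shape[1], note=note,
                         embedding_params=emb_params)


def fibroblast_sharing(matrix: pd.DataFrame, fibro_calls: pd.DataFrame | None,
                       threshold: float = CARRIER_THRESHOLD,
                       ) -> tuple[pd.DataFrame, dict]:
    """Label single-cell variants as fibroblast-shared or stage-specific.

    A variant is fibroblast-shared when the matched fibroblast bulk calls
    contain it (any AF ≥ 2 %).  The summary reports what fraction of the
    shared variants is carried by > 95 % and > 50 % of cells.  Variant
    column names follow ``<position><ref>><alt>``.
    """
    carrier_prop = (matrix >= threshold).mean(axis=0)
    if fibro_calls is None or len(fibro_calls) == 0:
        labels = pd.DataFrame({
            "variant": matrix.columns,
            "label": "stage_specific",
            "carrier_proportion": carrier_prop.values,
        })
        return labels, {"warning": "no matched fibroblast calls",
                        "n_shared": 0, "frac_gt95": None, "frac_gt50": None}
    present = fibro_calls[fibro_calls["allele_fraction"] >= threshold]
    fib_keys = {f"{int(p)}{r}>{a}" for p, r, a in
                zip(present["position"], present["ref"], present["alt"])}
    labels = pd.DataFrame({
        "variant": matrix.columns,
        "label": [("fibroblast_shared" if v in fib_keys else "stage_specific")
                  for v in matrix.columns],
        "carrier_proportion": carrier_prop.values,
    })
    shared = labels[labels["label"] == "fibroblast_shared"]
    n_shared = len(shared)
    summary = {
        "n_shared": n_shared,
        "frac_gt95": (float((shared["carrier_proportion"] > 0.95).mean())
                      if n_shared else None),
        "frac_gt50": (float((shared["carrier_proportion"] > 0.50).mean())
                      if n_shared else None),
    }
    return labels, summary
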