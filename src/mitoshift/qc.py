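"""Variant-, sample- and cell-level quality control.

Implements the filtering rules used for deep mtDNA sequencing of bulk WGS,
bulk RNA-seq and single-cell RNA-seq data.  Variant calls are plain pandas
DataFrames with the columns::

    sample_id, position, ref, alt, allele_fraction, depth,
    alt_forward, alt_reverse, source

Filters are applied in a fixed order so that per-rule removal counts are
reproducible; a :class:`FilterReport` reconciles exactly with the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import MitoReference

VALID_MODES = ("wgs_bulk", "rna_bulk", "scrna")

#: mtRNA-specific artefact sites removed from bulk RNA-seq calls.
RNA_ARTEFACT_SITES = {
    (2617, "A", "G"), (2129, "G", "A"), (295, "C", "T"),
    (5746, "G", "A"), (13710, "A", "G"), (5985, "G", "T"),
}

CALL_COLUMNS = ["sample_id", "position", "ref", "alt", "allele_fraction",
                "depth", "alt_forward", "alt_reverse", "source"]


@dataclass
class FilterReport:
    """Per-rule removal counts; ``removed + retained == n_input``."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


_SNV_ALLELES = {"A", "C", "G", "T"}


def filter_variant_calls(calls: pd.DataFrame, ref: MitoReference,
                         mode: str = "wgs_bulk", *, min_af: float = 0.02,
                         min_depth: int = 200, min_strand_reads: int = 2,
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the variant-level filters in their fixed order.

    Order: SNV-only → AF ≥ 2 % → depth ≥ 200× → ≥ 2 alt reads on each
    strand → low-complexity exclusion → (rna_bulk) artefact-site removal.
    """
    if mode not in VALID_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {VALID_MODES}")
    calls = calls.copy()
    report = FilterReport(n_input=len(calls))

    ref_u = calls["ref"].astype(str).str.upper()
    alt_u = calls["alt"].astype(str).str.upper()
    malformed = ~(ref_u.str.fullmatch(r"[ACGTN\-]+") & alt_u.str.fullmatch(r"[ACGTN\-]+"))
    if malformed.any():
        rows = calls.index[malformed].tolist()[:10]
        raise ValueError(f"malformed alleles in rows {rows}")

    def drop(mask: pd.Series, rule: str):
        nonlocal calls
        report.removed[rule] = int(mask.sum())
        calls = calls[~mask]

    is_snv = (calls["ref"].astype(str).str.len() == 1) \
        & (calls["alt"].astype(str).str.len() == 1) \
        & calls["ref"].astype(str).str.upper().isin(_SNV_ALLELES) \
        & calls["alt"].astype(str).str.upper().isin(_SNV_ALLELES)
    drop(~is_snv, "not_snv")
    drop(calls["allele_fraction"] < min_af, "low_af")
    drop(calls["depth"] < min_depth, "low_depth")
    drop((calls["alt_forward"] < min_strand_reads)
         | (calls["alt_reverse"] < min_strand_reads), "strand_support")
    lc = calls["position"].map(ref.in_low_complexity)
    drop(lc.astype(bool), "low_complexity")
    if mode == "rna_bulk":
        key = list(zip(calls["position"], calls["ref"].str.upper(),
                       calls["alt"].str.upper()))
        artefact = pd.Series([k in RNA_ARTEFACT_SITES for k in key],
                             index=calls.index)
        drop(artefact, "rna_artefact")
    report.n_retained = len(calls)
    return calls.reset_index(drop=True), report


def call_heteroplasmy_state(allele_fraction: float, mode: str = "wgs_bulk") -> str:
    """Classify an allele fraction as absent / heteroplasmic / homoplasmic.

    Bulk modes use the 2–98 % heteroplasmy band; single-cell uses 2–95 %
    (boundaries inclusive on the heteroplasmic side).
    """
    if mode not in VALID_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 <= allele_fraction <= 1:
        raise ValueError("allele fraction outside [0, 1]")
    high = 0.95 if mode == "scrna" else 0.98
    if allele_fraction < 0.02:
        return "absent"
    if allele_fraction <= high:
        return "heteroplasmic"
    return "homoplasmic"


def sample_qc(samples: pd.DataFrame, calls: pd.DataFrame, *,
              min_mean_depth: float = 400.0, contamination_shared: int = 10,
              hf_tolerance: float = 0.05) -> pd.DataFrame:
    """Sample-level pass/fail with reasons.

    Fails samples with mean mtDNA depth < 400×; fails *both* members of any
    pair sharing more than ``contamination_shared`` heteroplasmic variants at
    similar HFs (|ΔHF| ≤ ``hf_tolerance``, a configurable stand-in for the
    contamination check); fails iPSC lines without a passing matched
    fibroblast.
    """
    reasons: dict[str, list[str]] = {s: [] for s in samples["line_id"]}

    depth_fail = samples[samples["mean_mtdna_depth"] < min_mean_depth]
    for s in depth_fail["line_id"]:
        reasons[s].append("depth")

    het = calls[(calls["allele_fraction"] >= 0.02)
                & (calls["allele_fraction"] <= 0.98)]
    by_sample = {s: g.set_index("position")["allele_fraction"]
                 for s, g in het.groupby("sample_id")}
    ids = [s for s in samples["line_id"] if s in by_sample]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = by_sample[a].index.intersection(by_sample[b].index)
            if len(shared) <= contamination_shared:
                continue
            close = (by_sample[a].loc[shared] - by_sample[b].loc[shared]).abs() <= hf_tolerance
            if int(close.sum()) > contamination_shared:
                reasons[a].append("contamination")
                reasons[b].append("contamination")

    passing_fibro = {
        r["donor_id"] for _, r in samples.iterrows()
        if r["tissue"] == "fibroblast" and not reasons[r["line_id"]]
    }
    for _, r in samples.iterrows():
        if r["tissue"] == "iPSC" and r["donor_id"] not in passing_fibro:
            reasons[r["line_id"]].append("unmatched")

    return pd.DataFrame({
        "line_id": samples["line_id"],
        "passed": [not reasons[s] for s in samples["line_id"]],
        "reasons": [",".join(sorted(set(reasons[s]))) for s in samples["line_id"]],
    })


def cell_qc(cell_calls: pd.DataFrame, cell_meta: pd.DataFrame,
            ref: MitoReference, *, min_cell_depth: float = 200.0,
            max_heteroplasmies: int = 20, site_depth: pd.Series | None = None,
            min_region_depth: float = 200.0) -> tuple[pd.DataFrame, dict]:
    """Single-cell QC: the five filtering rules for scRNA-derived variants.

    ``cell_calls`` columns: cell_id, position, ref, alt, allele_fraction,
    depth.  ``cell_meta`` columns: cell_id, line_id, stage, mean_mtdna_depth.
    ``site_depth`` (optional): per-position mean depth used for the ≥200×
    region mask; positions below the cutoff are dropped and reported.
    """
    report: dict = {}
    calls = cell_calls.merge(cell_meta[["cell_id", "line_id", "stage"]],
                             on="cell_id", how="left")

    # (1) cell depth
    deep = set(cell_meta.loc[cell_meta["mean_mtdna_depth"] >= min_cell_depth,
                             "cell_id"])
    report["cells_low_depth"] = int((~cell_meta["cell_id"].isin(deep)).sum())
    calls = calls[calls["cell_id"].isin(deep)]

    # (5) region mask (applied before counting so masked sites never count)
    if site_depth is not None:
        keep_sites = set(site_depth.index[site_depth >= min_region_depth])
        report["sites_masked"] = int((~pd.Index(site_depth.index).isin(keep_sites)).sum())
        report["retained_bases"] = len(keep_sites)
        calls = calls[calls["position"].isin(keep_sites)]
    else:
        report["retained_bases"] = None

    # (3) heteroplasmy band (2-95%): homoplasmies kept as homoplasmic, <2% dropped
    state = calls["allele_fraction"].map(
        lambda af: call_heteroplasmy_state(af, "scrna"))
    report["subthreshold_calls"] = int((state == "absent").sum())
    calls = calls[state != "absent"]
    state = state[state != "absent"]

    # (2) stage-specific variants seen in exactly one cell of a line
    key = ["line_id", "stage", "position", "ref", "alt"]
    n_cells = calls.groupby(key)["cell_id"].transform("nunique")
    singleton = n_cells == 1
    report["singleton_variants"] = int(singleton.sum())
    calls = calls[~singleton]

    # (4) cells with too many heteroplasmic variants
    het_mask = calls["allele_fraction"] <= 0.95
    n_het = calls[het_mask].groupby("cell_id")["position"].count()
    noisy = set(n_het.index[n_het > max_heteroplasmies])
    report["cells_too_many_heteroplasmies"] = len(noisy)
    calls = calls[~calls["cell_id"].isin(noisy)]

    report["retained_calls"] = len(calls)
    report["retained_cells"] = int(calls["cell_id"].nunique())
    return calls.reset_index(drop=True), report
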