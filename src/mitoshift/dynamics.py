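"""Fibroblast→iPSC variant dynamics: classification, heteroplasmic shifts,
mutation rates, selection ratios, region enrichment and regression models.

Variants detected at HF ≥ 2 % in a fibroblast line and its derived iPSC
line are classified as *shared* (present in both), *lost* (fibroblast only)
or *iPSC-specific* (iPSC only).  Shared variants get a heteroplasmic shift
HS = log2(HF_iPSC / HF_fibroblast); the excess of positive shifts is tested
with an exact binomial test.  iPSC-specific events, after rescuing variants
present in the fibroblast below the detection threshold, yield a mutation
rate per base pair per genome per reprogramming with an exact Poisson CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .reference import MT_LENGTH, MitoReference, RegionClass

DETECTION_THRESHOLD = 0.02


def percent(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded as printed in cohort summaries."""
    if n == 0:
        raise ValueError("denominator is zero")
    return round(100.0 * k / n, decimals)


# -- pairing and classification ------------------------------------------------


def pair_lines(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """One (fibroblast, iPSC) pair per iPSC line; orphan iPSCs are skipped.

    Two iPSCs from the same fibroblast form two separate pairs.
    """
    fibro = samples[samples["tissue"] == "fibroblast"]
    by_donor = fibro.groupby("donor_id")["line_id"].first()
    pairs = []
    for _, r in samples[samples["tissue"] == "iPSC"].iterrows():
        if r["donor_id"] in by_donor.index:
            pairs.append((by_donor[r["donor_id"]], r["line_id"]))
    return pairs


def _hf_map(calls: pd.DataFrame, sample: str) -> dict:
    sub = calls[calls["sample_id"] == sample]
    return {(int(p), rf, al): af for p, rf, al, af in
            zip(sub["position"], sub["ref"], sub["alt"],
                sub["allele_fraction"])}


def classify_pair(pair: tuple[str, str], fibro_calls: pd.DataFrame,
                  ipsc_calls: pd.DataFrame, ref: MitoReference | None = None,
                  threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Classify every variant of one fibroblast–iPSC pair.

    shared: ≥ threshold in both (heteroplasmic in at least one member);
    lost: heteroplasmic in the fibroblast, < threshold in the iPSC;
    ipsc_specific: ≥ threshold in the iPSC, < threshold in the fibroblast.
    """
    fibro_line, ipsc_line = pair
    f = _hf_map(fibro_calls, fibro_line)
    i = _hf_map(ipsc_calls, ipsc_line)
    rows = []
    for key in sorted(set(f) | set(i)):
        hf_f, hf_i = f.get(key, 0.0), i.get(key, 0.0)
        in_f, in_i = hf_f >= threshold, hf_i >= threshold
        if not in_f and not in_i:
            continue
        het_f = threshold <= hf_f <= 0.98
        het_i = threshold <= hf_i <= 0.98
        if in_f and in_i:
            if not (het_f or het_i):
                continue  # homoplasmic in both: haplogroup marker, not a dynamic
            category = "shared"
        elif het_f and not in_i:
            category = "lost"
        elif in_i and not in_f:
            category = "ipsc_specific"
        else:
            continue  # homoplasmic fibroblast variant absent in iPSC
        pos, rf, al = key
        row = {"donor": None, "fibroblast_line": fibro_line,
               "ipsc_line": ipsc_line, "position": pos, "ref": rf, "alt": al,
               "hf_fibro": hf_f, "hf_ipsc": hf_i, "category": category}
        if ref is not None:
            row["region"] = ref.classify_variant_region(pos, rf, al).value
            row["pathogenic"] = (pos, al) in ref.pathogenic_sites
        rows.append(row)
    return pd.DataFrame(rows)


def classify_duo(fibro_calls: pd.DataFrame, ipsc_calls_1: pd.DataFrame,
                 ipsc_calls_2: pd.DataFrame, lines: tuple[str, str, str],
                 threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Sub-categories for a fibroblast with two derived iPSC lines.

    Fibroblast heteroplasmies partition into shared_both / shared_one /
    lost_both; iPSC variants absent from the fibroblast partition into
    ipsc_specific_both / ipsc_specific_one.
    """
    fl, il1, il2 = lines
    f = _hf_map(fibro_calls, fl)
    i1 = _hf_map(ipsc_calls_1, il1)
    i2 = _hf_map(ipsc_calls_2, il2)
    rows = []
    for key in sorted(set(f) | set(i1) | set(i2)):
        hf_f = f.get(key, 0.0)
        hf_a, hf_b = i1.get(key, 0.0), i2.get(key, 0.0)
        in_f = hf_f >= threshold
        in_a, in_b = hf_a >= threshold, hf_b >= threshold
        het_any = any(threshold <= h <= 0.98 for h in (hf_f, hf_a, hf_b))
        if in_f:
            if not het_any:
                continue
            if in_a and in_b:
                sub = "shared_both"
            elif in_a or in_b:
                sub = "shared_one"
            else:
                sub = "lost_both"
        elif in_a and in_b:
            sub = "ipsc_specific_both"
        elif in_a or in_b:
            sub = "ipsc_specific_one"
        else:
            continue
        pos, rf, al = key
        rows.append({"fibroblast_line": fl, "position": pos, "ref": rf,
                     "alt": al, "hf_fibro": hf_f, "hf_ipsc_1": hf_a,
                     "hf_ipsc_2": hf_b, "duo_subcategory": sub})
    return pd.DataFrame(rows)


# -- heteroplasmic shift -------------------------------------------------------


def heteroplasmic_shift(hf_fibro: float, hf_ipsc: float) -> float:
    """HS = log2(HF_iPSC / HF_fibroblast); defined for shared variants only."""
    if hf_fibro <= 0 or hf_ipsc <= 0:
        raise ValueError("heteroplasmic shift requires both HFs > 0; "
                         "restrict to shared variants or supply a floor")
    return float(np.log2(hf_ipsc / hf_fibro))


def shift_records(classified: pd.DataFrame, samples: pd.DataFrame | None = None,
                  extreme_threshold: float = 6.0) -> pd.DataFrame:
    """ShiftRecord table for shared variants: hs, direction, extreme flag."""
    shared = classified[classified["category"] == "shared"].copy()
    if shared.empty:
        return shared.assign(hs=[], direction=[], extreme=[])
    shared["hs"] = [heteroplasmic_shift(f, i) for f, i in
                    zip(shared["hf_fibro"], shared["hf_ipsc"])]
    shared["direction"] = np.where(shared["hs"] > 0, "increase", "decrease")
    shared["extreme"] = shared["hs"] > extreme_threshold
    shared["hf_fibro_logit"] = np.log(shared["hf_fibro"]
                                      / (1 - shared["hf_fibro"]))
    if samples is not None:
        meta = samples.set_index("line_id")
        shared["age"] = shared["ipsc_line"].map(meta["age"])
        shared["haplogroup"] = shared["ipsc_line"].map(meta["macro_haplogroup"])
    return shared


def direction_binomial(n_increase: int, n_total: int,
                       ) -> tuple[float, float, float]:
    """Exact binomial test of the increase proportion against 0.5.

    Returns (two-sided p, Clopper–Pearson 95 % CI low, high).
    """
    if n_total == 0:
        raise ValueError("n_total must be > 0")
    test = stats.binomtest(n_increase, n_total, p=0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return float(test.pvalue), float(ci.low), float(ci.high)


# -- mutation rates ------------------------------------------------------------


@dataclass
class RateEstimate:
    n_events: int
    n_lines: int
    rate_per_bp_per_genome: float
    ci_low: float
    ci_high: float
    rate_per_bp_per_molecule: float | None = None
    n_rescued: int | None = None
    rescue_applied: bool = True


def _poisson_ci(k: int, denominator: float, level=0.95) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return lo / denominator, hi / denominator


def specific_mutation_rate(classified: pd.DataFrame, n_lines: int,
                           fibro_calls_unfiltered: pd.DataFrame | None = None,
                           *, pathogenic_only: bool = False,
                           ref: MitoReference | None = None,
                           copies_per_cell: float | None = None,
                           ) -> RateEstimate:
    """iPSC-specific mutation rate per bp per genome per reprogramming.

    iPSC-specific variants whose matched fibroblast shows *any* supporting
    reads (AF > 0 in the unfiltered calls) are rescued as pre-existing and
    excluded from the event count.  rate = events / (16,569 × n_lines), with
    an exact Poisson 95 % CI; the per-molecule rate divides by an explicit
    copies-per-cell normaliser.
    """
    spec = classified[classified["category"] == "ipsc_specific"].copy()
    if pathogenic_only:
        if "pathogenic" in spec.columns:
            spec = spec[spec["pathogenic"].astype(bool)]
        elif ref is not None:
            keep = [(p, a) in ref.pathogenic_sites
                    for p, a in zip(spec["position"], spec["alt"])]
            spec = spec[keep]
        else:
            raise ValueError("pathogenic_only needs a pathogenic annotation")
    n_rescued = None
    rescued = np.zeros(len(spec), dtype=bool)
    if fibro_calls_unfiltered is not None and len(spec):
        raw = {(s, int(p), rf, al): af for s, p, rf, al, af in zip(
            fibro_calls_unfiltered["sample_id"],
            fibro_calls_unfiltered["position"],
            fibro_calls_unfiltered["ref"], fibro_calls_unfiltered["alt"],
            fibro_calls_unfiltered["allele_fraction"])}
        rescued = np.array([
            raw.get((fl, int(p), rf, al), 0.0) > 0
            for fl, p, rf, al in zip(spec["fibroblast_line"], spec["position"],
                                     spec["ref"], spec["alt"])])
        n_rescued = int(rescued.sum())
    n_events = int(len(spec) - rescued.sum())
    denom = MT_LENGTH * n_lines
    rate = n_events / denom
    lo, hi = _poisson_ci(n_events, denom)
    per_mol = rate / copies_per_cell if copies_per_cell else None
    return RateEstimate(n_events=n_events, n_lines=n_lines,
                        rate_per_bp_per_genome=rate, ci_low=lo, ci_high=hi,
                        rate_per_bp_per_molecule=per_mol, n_rescued=n_rescued,
                        rescue_applied=fibro_calls_unfiltered is not None)


def threshold_sensitivity(pairs: list[tuple[str, str]],
                          fibro_calls_unfiltered: pd.DataFrame,
                          ipsc_calls_unfiltered: pd.DataFrame,
                          thresholds=(0.02, 0.015, 0.01, 0.005),
                          ) -> pd.DataFrame:
    """Specific-mutation rate as the iPSC detection threshold is lowered.

    The fibroblast presence rule (any supporting reads → pre-existing) is
    held fixed; only the iPSC detection threshold moves, so the rate is
    monotone non-decreasing as the threshold falls.
    """
    n_lines = len(pairs)
    fib = {(s, int(p), rf, al): af for s, p, rf, al, af in zip(
        fibro_calls_unfiltered["sample_id"], fibro_calls_unfiltered["position"],
        fibro_calls_unfiltered["ref"], fibro_calls_unfiltered["alt"],
        fibro_calls_unfiltered["allele_fraction"])}
    rows = []
    for t in sorted(thresholds, reverse=True):
        n_events = 0
        for fibro_line, ipsc_line in pairs:
            sub = ipsc_calls_unfiltered[
                (ipsc_calls_unfiltered["sample_id"] == ipsc_line)
                & (ipsc_calls_unfiltered["allele_fraction"] >= t)]
            for p, rf, al in zip(sub["position"], sub["ref"], sub["alt"]):
                if fib.get((fibro_line, int(p), rf, al), 0.0) <= 0:
                    n_events += 1
        rows.append({"threshold": t, "n_events": n_events,
                     "rate_per_bp_per_genome": n_events / (MT_LENGTH * n_lines)})
    return pd.DataFrame(rows)


# -- selection and region statistics -------------------------------------------


def nsss_ratio(variants: pd.DataFrame) -> float | None:
    """Nonsynonymous / synonymous count ratio over coding-region variants."""
    ns = int((variants["region"] == RegionClass.NONSYNONYMOUS.value).sum())
    ss = int((variants["region"] == RegionClass.SYNONYMOUS.value).sum())
    if ss == 0:
        return None if ns else 0.0
    return ns / ss


def coding_opportunity_ratio(ref: MitoReference) -> float:
    """NS/SS opportunity ratio: enumerate all coding substitutions of the
    reference and count how many are nonsynonymous vs synonymous."""
    ns = ss = 0
    for g in ref.genes:
        if g.kind != "protein":
            continue
        for pos in range(g.start, g.end + 1):
            if ref.features_at(pos)[0] is not g:
                continue
            base = ref.base(pos)
            for alt in "ACGT":
                if alt == base:
                    continue
                cls = ref.classify_variant_region(pos, base, alt)
                if cls == RegionClass.NONSYNONYMOUS:
                    ns += 1
                elif cls == RegionClass.SYNONYMOUS:
                    ss += 1
    return ns / ss


def region_mutation_frequency(variants: pd.DataFrame, ref: MitoReference,
                              n_lines: int) -> pd.DataFrame:
    """Per-region mutation frequency with Fisher enrichment tests.

    frequency = count / (region length × n_lines).  ``fisher_vs_rest``
    tests the region's count against all other regions; ``fisher_vs_expected``
    tests it against the genome-wide average.  Raw p-values are reported
    alongside Benjamini–Hochberg adjustment.
    """
    kind_of = {"dloop": "dloop", "protein": "coding", "rRNA": "rRNA",
               "tRNA": "tRNA", "noncoding": "noncoding"}
    lengths: dict[str, int] = {}
    for k, n in ref.region_lengths().items():
        kk = kind_of.get(k, "noncoding")
        lengths[kk] = lengths.get(kk, 0) + n
    counts = {k: 0 for k in lengths}
    for pos in variants["position"]:
        counts[kind_of.get(ref.feature_kind(int(pos)), "noncoding")] += 1
    total_count = sum(counts.values())
    total_len = sum(lengths.values())
    rows = []
    for region, length in lengths.items():
        c = counts[region]
        opp = length * n_lines
        # region vs rest of genome
        rest_c = total_count - c
        rest_opp = (total_len - length) * n_lines
        _, p_rest = stats.fisher_exact(
            [[c, opp - c], [rest_c, rest_opp - rest_c]])
        # region vs genome-wide expectation
        _, p_exp = stats.fisher_exact(
            [[c, opp - c], [total_count, total_len * n_lines - total_count]])
        rows.append({"region": region, "n_variants": c, "length_bp": length,
                     "frequency_per_bp": c / opp,
                     "fisher_vs_rest_p": p_rest,
                     "fisher_vs_expected_p": p_exp})
    out = pd.DataFrame(rows)
    for col in ("fisher_vs_rest_p", "fisher_vs_expected_p"):
        out[col + "_bh"] = multipletests(out[col], method="fdr_bh")[1]
    return out


def relative_copy_number(mean_mtdna_depth: float,
                         mean_autosomal_depth: float) -> float:
    """Relative mtDNA copies per diploid cell: 2 × DPmt / DPautosome."""
    if mean_autosomal_depth <= 0:
        raise ValueError("autosomal depth must be > 0")
    return 2.0 * mean_mtdna_depth / mean_autosomal_depth


# -- regression models ---------------------------------------------------------


def _haplogroup_term(df: pd.DataFrame, col: str = "macro_haplogroup") -> str:
    if df[col].nunique() < 2:
        return ""
    refcat = df[col].mode().iloc[0]
    return f" + C({col}, Treatment(reference='{refcat}'))"


def fit_age_models(samples: pd.DataFrame, burden: pd.Series,
                   mean_hf: pd.Series) -> dict[str, pd.DataFrame]:
    """OLS of heteroplasmy burden and logit mean HF on age + sex + haplogroup.

    ``burden`` and ``mean_hf`` are indexed by line_id.  Models are fitted
    separately for fibroblast (models 1 and 3) and iPSC lines (2 and 4);
    single-level covariates are dropped with a warning column in the output.
    """
    out = {}
    for tissue, b_name, h_name in (("fibroblast", "burden_fibroblast",
                                    "mean_hf_fibroblast"),
                                   ("iPSC", "burden_ipsc", "mean_hf_ipsc")):
        sub = samples[samples["tissue"] == tissue].copy()
        if len(sub) < 10:
            continue
        sub["burden"] = sub["line_id"].map(burden)
        hf = sub["line_id"].map(mean_hf).clip(1e-4, 1 - 1e-4)
        sub["hf_logit"] = np.log(hf / (1 - hf))
        sub = sub.dropna(subset=["burden", "age"])
        hap = _haplogroup_term(sub)
        sex = " + C(sex)" if sub["sex"].nunique() > 1 else ""
        for resp, name in (("burden", b_name), ("hf_logit", h_name)):
            data = sub.dropna(subset=[resp])
            fit = smf.ols(f"{resp} ~ age{sex}{hap}", data=data).fit()
            out[name] = pd.DataFrame({"estimate": fit.params,
                                      "se": fit.bse, "p": fit.pvalues})
    return out


def fit_shift_direction_model(shifts: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of shift direction (model of increase vs decrease).

    S = 1 if HS > 0, regressed on logit fibroblast HF, region class (D-loop
    reference level), haplogroup and donor age.  Complete separation falls
    back to an L2-penalised fit, flagged in the output attrs.
    """
    df = shifts.copy()
    if df["direction"].nunique() < 2:
        out = pd.DataFrame(columns=["estimate", "se", "p"])
        out.attrs["separation"] = True
        return out
    df["S"] = (df["hs"] > 0).astype(int)
    terms = ["hf_fibro_logit", "C(region, Treatment(reference='dloop'))"]
    if "haplogroup" in df and df["haplogroup"].nunique() > 1:
        terms.append("C(haplogroup)")
    if "age" in df and df["age"].nunique() > 1:
        terms.append("age")
    formula = "S ~ " + " + ".join(terms)
    separated = False
    try:
        fit = smf.logit(formula, data=df).fit(disp=0)
        if not fit.mle_retvals.get("converged", True) or fit.bse.max() > 50:
            raise PerfectSeparationError("inflated standard errors")
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        model = smf.logit(formula, data=df)
        fit = model.fit_regularized(alpha=1.0, disp=0)
        params = fit.params
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
    out = pd.DataFrame({"estimate": params, "se": bse, "p": pvals})
    out.attrs["separation"] = separated
    return out
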