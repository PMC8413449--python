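"""Readers/writers for variant tables, matrices and run configuration, plus
the end-to-end synthetic pipeline driver.

Variant tables travel as TSV (the columns of :data:`mitoshift.qc.CALL_COLUMNS`)
or as VCF with per-sample FORMAT fields ``AF`` (alt allele fraction), ``DP``
(site depth) and ``SAF``/``SAR`` (alt-supporting reads on the forward and
reverse strand).  Cell × variant matrices round-trip through MatrixMarket
with TSV sidecars.  Every randomised stage records its seed in the summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from scipy import io as spio
from scipy import sparse

from . import dynamics, signatures
from .qc import CALL_COLUMNS, filter_variant_calls
from .reference import MT_LENGTH, MitoReference, default_reference
from .simulate import (SimulationParams, simulate_fibroblast_cohort,
                       simulate_read_counts, simulate_reprogramming)

# -- variant tables ------------------------------------------------------------


def read_variant_table(path, dialect: str = "tsv",
                       source: str = "wgs_bulk") -> pd.DataFrame:
    """Read a variant call table; indel records are excluded and counted.

    The number of excluded indel records is available as
    ``df.attrs['n_indels_excluded']``.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if missing := set(CALL_COLUMNS) - {"source"} - set(df.columns):
            raise ValueError(f"missing mandatory columns: {sorted(missing)}")
        if "source" not in df.columns:
            df["source"] = source
    elif dialect == "vcf":
        rows = []
        n_indels = 0
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) != 1 or len(alt) != 1:
                        n_indels += 1
                        continue
                    for sample_name, call in rec.samples.items():
                        af = call.get("AF")
                        if af is None:
                            continue
                        af = af[0] if isinstance(af, tuple) else af
                        if af is None:
                            continue
                        adf = call.get("SAF", 0) or 0
                        adr = call.get("SAR", 0) or 0
                        rows.append({
                            "sample_id": sample_name, "position": rec.pos,
                            "ref": rec.ref, "alt": alt,
                            "allele_fraction": float(af),
                            "depth": int(call.get("DP") or 0),
                            "alt_forward": int(adf), "alt_reverse": int(adr),
                            "source": source,
                        })
        df = pd.DataFrame(rows, columns=CALL_COLUMNS)
        df.attrs["n_indels_excluded"] = n_indels
        return df
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.attrs.setdefault("n_indels_excluded", 0)
    return df


def write_variant_table(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_variant_vcf(calls: pd.DataFrame, path, contig: str = "chrM") -> None:
    """Write calls as a multi-sample VCF with AF/DP/SAF/SAR FORMAT fields."""
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=MT_LENGTH)
    header.formats.add("AF", 1, "Float", "Alt allele fraction")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.formats.add("SAF", 1, "Integer", "Alt reads, forward strand")
    header.formats.add("SAR", 1, "Integer", "Alt reads, reverse strand")
    samples = sorted(calls["sample_id"].unique())
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        grouped = calls.groupby(["position", "ref", "alt"], sort=True)
        for (pos, ref_a, alt_a), grp in grouped:
            rec = out.new_record(contig=contig, start=int(pos) - 1,
                                 alleles=(str(ref_a), str(alt_a)))
            by_sample = grp.set_index("sample_id")
            for s in samples:
                if s in by_sample.index:
                    r = by_sample.loc[s]
                    rec.samples[s]["AF"] = float(r["allele_fraction"])
                    rec.samples[s]["DP"] = int(r["depth"])
                    rec.samples[s]["SAF"] = int(r["alt_forward"])
                    rec.samples[s]["SAR"] = int(r["alt_reverse"])
            out.write(rec)


# -- matrices ------------------------------------------------------------------


def write_cell_matrix(matrix: pd.DataFrame, prefix) -> None:
    """cells × variants HF matrix as MTX plus row/column TSV sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(matrix.to_numpy()))
    prefix.with_suffix(".cells.tsv").write_text(
        "\n".join(matrix.index) + "\n")
    prefix.with_suffix(".variants.tsv").write_text(
        "\n".join(map(str, matrix.columns)) + "\n")


def read_cell_matrix(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    cells = prefix.with_suffix(".cells.tsv").read_text().splitlines()
    variants = prefix.with_suffix(".variants.tsv").read_text().splitlines()
    return pd.DataFrame(m, index=cells, columns=variants)


# -- configuration -------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run configuration with the study's default thresholds."""

    output_dir: str = "mitoshift_out"
    mode: str = "wgs_bulk"
    seed: int = 0
    min_af: float = 0.02
    min_depth: int = 200
    min_strand_reads: int = 2
    hf_homoplasmy_bulk: float = 0.98
    hf_homoplasmy_sc: float = 0.95
    n_donors: int = 40
    n_ipsc_per_donor: int = 1
    variant_table: str | None = None   # external input; None -> simulate
    sample_table: str | None = None
    simulation: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# -- pipeline ------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary(results: dict, path) -> None:
    """Machine-readable JSON summary; absent statistics stay null."""
    Path(path).write_text(json.dumps(_jsonable(results), indent=2,
                                     allow_nan=True))


def run_pipeline(config: RunConfig, ref: MitoReference | None = None) -> dict:
    """filter → classify → shift → rate → signatures on a cohort.

    With no external inputs a synthetic cohort is generated at
    ``config.seed``; all tables and a JSON summary land in
    ``config.output_dir``.
    """
    ref = ref or default_reference()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.variant_table:
        calls_raw = read_variant_table(config.variant_table)
        samples = pd.read_csv(config.sample_table, sep="\t")
    else:
        params = SimulationParams(seed=config.seed,
                                  n_donors=config.n_donors,
                                  **config.simulation)
        fib_samples, fib_truth = simulate_fibroblast_cohort(params, ref)
        ipsc_samples, ipsc_truth = simulate_reprogramming(
            fib_samples, fib_truth, params, config.n_ipsc_per_donor, ref)
        samples = pd.concat([fib_samples, ipsc_samples], ignore_index=True)
        calls_raw = simulate_read_counts(
            pd.concat([fib_truth, ipsc_truth], ignore_index=True), params,
            source=config.mode, ref=ref)

    filtered, report = filter_variant_calls(
        calls_raw, ref, config.mode, min_af=config.min_af,
        min_depth=config.min_depth, min_strand_reads=config.min_strand_reads)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    write_variant_table(filtered, out / "filtered_calls.tsv")

    pairs = dynamics.pair_lines(samples)
    classified = pd.concat(
        [dynamics.classify_pair(p, filtered, filtered, ref) for p in pairs],
        ignore_index=True) if pairs else pd.DataFrame()
    if len(classified):
        classified.to_csv(out / "classified_variants.tsv", sep="\t",
                          index=False)

    summary: dict = {"seed": config.seed, "n_pairs": len(pairs),
                     "filter": report.removed,
                     "n_retained_calls": report.n_retained}
    if len(classified):
        cats = classified["category"].value_counts()
        n_shared = int(cats.get("shared", 0))
        n_lost = int(cats.get("lost", 0))
        n_spec = int(cats.get("ipsc_specific", 0))
        fib_total = n_shared + n_lost
        ipsc_total = n_shared + n_spec
        summary["shared_fraction"] = (n_shared / fib_total if fib_total
                                      else None)
        summary["lost_fraction"] = n_lost / fib_total if fib_total else None
        summary["specific_fraction"] = (n_spec / ipsc_total if ipsc_total
                                        else None)
        shifts = dynamics.shift_records(classified, samples)
        if len(shifts):
            shifts.to_csv(out / "shift_records.tsv", sep="\t", index=False)
            n_inc = int((shifts["direction"] == "increase").sum())
            p, lo, hi = dynamics.direction_binomial(n_inc, len(shifts))
            summary["direction"] = {"n_increase": n_inc,
                                    "n_total": len(shifts), "p": p,
                                    "ci": [lo, hi]}
        rate = dynamics.specific_mutation_rate(classified, len(pairs),
                                               calls_raw)
        summary["specific_rate"] = {
            "n_events": rate.n_events,
            "rate_per_bp_per_genome": rate.rate_per_bp_per_genome,
            "ci": [rate.ci_low, rate.ci_high]}
        if "region" in classified.columns:
            summary["nsss_ratio"] = dynamics.nsss_ratio(classified)
        spectrum = signatures.build_spectrum96(classified, ref)
        spectrum.rates.to_csv(out / "spectrum96_rates.tsv", sep="\t")
        summary["signature_total_variants"] = spectrum.total_variants
    else:
        summary.update({"shared_fraction": None, "lost_fraction": None,
                        "specific_fraction": None})
    write_summary(summary, out / "summary.json")
    return summary
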