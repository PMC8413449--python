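"""Strand-resolved mutational spectra on the circular mitochondrial genome.

Substitutions are expressed with a pyrimidine reference base (the six
classes C>A, C>G, C>T, T>A, T>C, T>G); the strand records which strand
carried that pyrimidine.  With the loaded FASTA treated as the L-strand
(configurable), a purine reference base means the pyrimidine sits on the H
strand and both alleles and the trinucleotide context are complemented.

The 96-class spectrum adds the immediate 5′ and 3′ bases; rates are counts
normalised by the trinucleotide context frequency of the reference on the
corresponding strand.  Spectra are compared per class with Fisher's exact
test and combined with Stouffer's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MitoReference, revcomp

PYRIMIDINES = ("C", "T")
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def context_labels() -> list[str]:
    """The conventional 96 context labels, e.g. ``A[C>A]A``."""
    out = []
    for cls in SIX_CLASSES:
        for five in "ACGT":
            for three in "ACGT":
                out.append(f"{five}[{cls}]{three}")
    return out


class SubstitutionClass(NamedTuple):
    pyrimidine_class: str  # one of SIX_CLASSES
    strand: str            # which strand carried the pyrimidine
    context: str           # 96-class label, e.g. T[C>T]A


def assign_substitution_class(ref_base: str, alt_base: str,
                              ref: MitoReference, position: int,
                              reference_strand: str = "L") -> SubstitutionClass:
    """Pyrimidine-oriented class, strand of origin and trinucleotide context."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("ref and alt alleles are identical")
    other = "H" if reference_strand == "L" else "L"
    tri = ref.trinucleotide_context(position)
    if ref_base in PYRIMIDINES:
        cls = f"{ref_base}>{alt_base}"
        strand = reference_strand
    else:
        cls = f"{_COMP[ref_base]}>{_COMP[alt_base]}"
        strand = other
        tri = revcomp(tri)
    context = f"{tri[0]}[{cls}]{tri[2]}"
    return SubstitutionClass(cls, strand, context)


@dataclass
class SignatureSpectrum:
    """Counts and context-normalised rates per substitution class and strand.

    ``counts`` and ``rates`` are DataFrames indexed by the 96 context labels
    with one column per strand; collapsing over contexts yields the 6-class
    spectrum exactly.
    """

    counts: pd.DataFrame
    rates: pd.DataFrame
    total_variants: int
    reference_strand: str = "L"
    strands: tuple = ("L", "H")

    def collapse6(self) -> pd.DataFrame:
        """6-class × strand counts (sum over contexts)."""
        cls = self.counts.index.str.extract(r"\[(.+)\]")[0].to_numpy()
        return self.counts.groupby(cls).sum()

    def class_frequencies(self) -> pd.Series:
        """Relative frequency of the six classes (both strands pooled)."""
        six = self.collapse6().sum(axis=1)
        total = six.sum()
        return six / total if total else six


def build_spectrum96(variants: pd.DataFrame, ref: MitoReference,
                     reference_strand: str = "L") -> SignatureSpectrum:
    """96-class strand-resolved spectrum of a variant table.

    ``variants`` needs columns position/ref/alt.  Rates divide each count by
    the frequency of its trinucleotide context on the strand that carried
    the pyrimidine.
    """
    labels = context_labels()
    counts = pd.DataFrame(0, index=labels, columns=["L", "H"])
    for pos, rf, al in zip(variants.get("position", []),
                           variants.get("ref", []), variants.get("alt", [])):
        sub = assign_substitution_class(rf, al, ref, int(pos), reference_strand)
        counts.loc[sub.context, sub.strand] += 1
    ctx_freq = {s: ref.context_frequencies(s) for s in ("L", "H")}
    rates = counts.astype(float).copy()
    for label in labels:
        tri = label[0] + label[2] + label[-1]  # 5' + pyrimidine + 3'
        for s in ("L", "H"):
            freq = ctx_freq[s].get(tri, 0)
            rates.loc[label, s] = counts.loc[label, s] / freq if freq else 0.0
    return SignatureSpectrum(counts=counts, rates=rates,
                             total_variants=int(counts.to_numpy().sum()),
                             reference_strand=reference_strand)


def spectrum6_by_region(variants: pd.DataFrame, ref: MitoReference,
                        reference_strand: str = "L") -> pd.DataFrame:
    """Per-region 6-class × strand relative frequencies (sum to 1 per region).

    ``variants`` needs position/ref/alt and a ``region`` column.
    """
    rows = []
    for region, grp in variants.groupby("region"):
        counts: dict[tuple, int] = {}
        for pos, rf, al in zip(grp["position"], grp["ref"], grp["alt"]):
            sub = assign_substitution_class(rf, al, ref, int(pos),
                                            reference_strand)
            key = (sub.pyrimidine_class, sub.strand)
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        for cls in SIX_CLASSES:
            for strand in ("L", "H"):
                rows.append({"region": region, "class": cls, "strand": strand,
                             "count": counts.get((cls, strand), 0),
                             "frequency": counts.get((cls, strand), 0) / total
                             if total else 0.0})
    return pd.DataFrame(rows)


# -- spectrum comparison -------------------------------------------------------


def stouffer_combine(pvalues, signs=None, two_sided: bool = True) -> tuple[float, float]:
    """Stouffer's Z from per-test p-values; returns (Z, combined one-sided p).

    Two-sided inputs require a direction sign per test: z_i = sign_i ·
    Φ⁻¹(1 − p_i/2), so that flat tests (p = 1 or sign 0) contribute zero.
    One-sided inputs use z_i = Φ⁻¹(1 − p_i) directly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if two_sided:
        s = np.ones_like(p) if signs is None else np.sign(np.asarray(signs, float))
        z = s * stats.norm.ppf(1 - np.clip(p, 1e-300, 1.0) / 2)
    else:
        z = stats.norm.ppf(1 - np.clip(p, 1e-300, 1 - 1e-16))
    Z = float(np.sum(z) / np.sqrt(len(z)))
    return Z, float(stats.norm.sf(Z))


def compare_spectra_stouffer(spectrum_a: SignatureSpectrum,
                             spectrum_b: SignatureSpectrum,
                             by: str = "class") -> tuple[pd.DataFrame, float]:
    """Per-class Fisher tests between two spectra plus a combined p-value.

    Each class count is tested against the remainder of its spectrum in a
    2×2 Fisher exact test (two-sided).  The evidence magnitudes
    z_i = Φ⁻¹(1 − p_i/2) are combined by Stouffer's method, so classes
    diverging in opposite directions reinforce rather than cancel, and
    identical spectra (all p = 1) combine to exactly 0.5.  Per-class odds
    ratios with CIs carry the direction.  Classes with an all-zero margin
    are skipped and noted.
    """
    if by == "class":
        a = spectrum_a.collapse6().sum(axis=1)
        b = spectrum_b.collapse6().sum(axis=1)
    else:
        a = spectrum_a.counts.sum(axis=1)
        b = spectrum_b.counts.sum(axis=1)
    tot_a, tot_b = int(a.sum()), int(b.sum())
    rows, pvals = [], []
    for cls in a.index:
        ka, kb = int(a[cls]), int(b[cls])
        if ka + kb == 0:
            rows.append({"class": cls, "skipped": True, "p": np.nan,
                         "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan})
            continue
        table = np.array([[ka, tot_a - ka], [kb, tot_b - kb]])
        res = stats.contingency.odds_ratio(table)
        p = float(stats.fisher_exact(table)[1])
        ci = res.confidence_interval(0.95)
        rows.append({"class": cls, "skipped": False, "p": p,
                     "odds_ratio": float(res.statistic),
                     "ci_low": float(ci.low), "ci_high": float(ci.high)})
        pvals.append(p)
    _, combined = stouffer_combine(pvals, two_sided=True)
    return pd.DataFrame(rows), combined


def correlate_signatures(spectrum: SignatureSpectrum,
                         external: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the spectrum with named external signatures.

    ``external`` is the conventional 96-row matrix with a ``context`` label
    column (e.g. ``A[C>A]A``) and one column per signature.  The spectrum's
    strand-summed rate vector is correlated with each signature column;
    returns R² and p per signature.
    """
    if "context" not in external.columns:
        raise ValueError("external matrix needs a 'context' column")
    expected = context_labels()
    got = list(external["context"])
    if got != expected:
        if sorted(got) == sorted(expected):
            external = external.set_index("context").loc[expected].reset_index()
        else:
            raise ValueError("external matrix context labels do not match the "
                             "96-class scheme")
    vec = spectrum.rates.sum(axis=1).to_numpy()
    rows = []
    for name in external.columns:
        if name == "context":
            continue
        other = external[name].to_numpy(dtype=float)
        r, p = stats.pearsonr(vec, other)
        rows.append({"signature": name, "r2": r * r, "p": p})
    return pd.DataFrame(rows)
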