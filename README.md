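# mitoshift

Mitochondrial DNA heteroplasmy dynamics through cell reprogramming.

Human cells carry hundreds to thousands of copies of the 16,569-bp
mitochondrial genome, and most people harbour *heteroplasmy*: sites where a
fraction of those copies carry an alternate allele. When fibroblasts are
reprogrammed into induced pluripotent stem cells (iPSCs), the heteroplasmy
landscape is reshaped — most age-related somatic variants are lost, the
survivors drift rapidly in fraction (consistent with a genetic bottleneck),
and new iPSC-specific mutations appear with a distinct mutational
signature. `mitoshift` implements the full analysis of this process for
deep mtDNA sequencing data, plus a synthetic cohort generator so every
stage is testable without access to a real cohort.

It is intended for researchers analysing matched fibroblast/iPSC mtDNA
variant calls (from bulk WGS, bulk RNA-seq, or single-cell RNA-seq), and
for methodologists who want a transparent, tested reference implementation
of the statistics involved.

## What it computes

* **Variant/sample/cell QC** — the detection rules for deep mtDNA
  sequencing: SNVs only, allele fraction (AF) ≥ 2 %, depth ≥ 200×, ≥ 2
  alt reads per strand, low-complexity exclusion
  (66–71, 300–316, 513–525, 3106–3107, 12418–12425, 16182–16194), RNA
  artefact sites, sample contamination and depth checks, and the
  five single-cell rules (`mitoshift.qc`).
* **Pair dynamics** — variants of each fibroblast→iPSC pair classified as
  *shared*, *lost*, or *iPSC-specific* (with duo sub-categories for donors
  with two derived lines); the heteroplasmic shift
  HS = log2(HF_iPSC / HF_fibro) with an exact binomial direction test
  (Clopper–Pearson CI); the iPSC-specific mutation rate
  λ = events / (16,569 · n_lines) with an exact Poisson CI, including the
  rescue of events present below the fibroblast detection threshold;
  NS/SS selection ratios, per-region mutation frequencies with Fisher
  enrichment tests, relative copy number CN_mt = 2·DP_mt/DP_autosome, and
  the linear (burden/HF vs age) and logistic (shift direction vs region)
  regression models (`mitoshift.dynamics`).
* **Mutational signatures** — strand-resolved 6- and 96-class substitution
  spectra with rates normalised to the trinucleotide context frequencies
  of the circular reference on each strand, per-class Fisher comparisons
  combined by Stouffer's method, and correlation against external
  96-class signature matrices (`mitoshift.signatures`).
* **Single-cell dynamics** — stage assignment from collection day and
  pseudotime, zero-inclusive pseudo-bulk heteroplasmy, carrier statistics,
  binned mutation frequencies, cross-stage concordance, and mtDNA-based
  clonal lineage recovery by hierarchical clustering with an optional UMAP
  embedding (`mitoshift.singlecell`).
* **Expression association** — per-gene variance partitioning into stage /
  batch / line / mtDNA-HF components and differential expression between
  genotype-defined sub-clones with Benjamini–Hochberg control
  (`mitoshift.expression`).
* **Synthetic cohorts** — age-dependent fibroblast burdens
  (count ~ Poisson(α + β·age)), beta-distributed heteroplasmy fractions,
  hotspot recurrence, a binomial bottleneck p′ = B/N with
  B ~ Binomial(N, p), signature-driven de novo mutations, binomial read
  sampling with strand splits, and single cells with latent clone
  structure and variant-linked expression effects (`mitoshift.simulate`).

The bundled reference couples the standard rCRS gene/region coordinates to
a deterministic **synthetic** base sequence (see `docs/methods.md`); load a
real rCRS FASTA with `mitoshift.load_reference` for real-data work.

## Worked example

```python
import pandas as pd
from mitoshift import default_reference, dynamics
from mitoshift.qc import filter_variant_calls
from mitoshift.simulate import (SimulationParams, simulate_fibroblast_cohort,
                                simulate_read_counts, simulate_reprogramming)

ref = default_reference()
params = SimulationParams(seed=1, n_donors=80)
fib_samples, fib_truth = simulate_fibroblast_cohort(params, ref)
ipsc_samples, ipsc_truth = simulate_reprogramming(fib_samples, fib_truth,
                                                  params, 1, ref)
calls_raw = simulate_read_counts(pd.concat([fib_truth, ipsc_truth]),
                                 params, ref=ref)
calls, report = filter_variant_calls(calls_raw, ref)

samples = pd.concat([fib_samples, ipsc_samples], ignore_index=True)
pairs = dynamics.pair_lines(samples)
classified = pd.concat(
    [dynamics.classify_pair(p, calls, calls, ref) for p in pairs],
    ignore_index=True)
shifts = dynamics.shift_records(classified, samples)
rate = dynamics.specific_mutation_rate(classified, len(pairs), calls_raw)
```

Running `python examples/bulk_pipeline.py` (the same analysis) prints:

```
filter removals: {'not_snv': 0, 'low_af': 996, 'low_depth': 0, 'strand_support': 0, 'low_complexity': 10} retained: 1014
80 pairs; shared 223, lost 453 (67.0 % of fibroblast heteroplasmies lost on reprogramming)
heteroplasmic shifts: 192/223 increased (exact binomial p = 1.5e-29, 95 % CI 0.809-0.904)
iPSC-specific rate: 108 events -> 8.15e-05 per bp per genome (95 % CI 6.68e-05-9.84e-05); 7 rescued as pre-existing below 2 %
```

Reading the numbers: two-thirds of the fibroblast heteroplasmies vanish
through the reprogramming bottleneck; among the survivors the heteroplasmy
fraction overwhelmingly increases (the binomial CI for the increase
proportion excludes 0.5 by a wide margin); and the iPSC-specific mutation
rate recovered from the noisy, filtered calls sits close to the simulated
truth of 8.6 × 10⁻⁵ per bp, with seven apparent "specific" events correctly
recognised as pre-existing fibroblast variants below the 2 % detection
threshold.

The other scripts in `examples/` demonstrate mutational signatures,
single-cell lineage tracing, and heteroplasmy–expression association, each
printing the quantities it computes and a line on how to read them.

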