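# Methods

This note documents the models, parameters and numerical choices behind
`mitoshift`, and what the synthetic cohorts do and do not establish about
real data.

## Reference model

The mitochondrial genome is treated as a 1-based circular sequence of
16,569 bases. The loaded FASTA strand is defined to be the light (L)
strand; the heavy (H) strand is its reverse complement. This labelling is
a convention, not a claim about replication chemistry — strand-resolved
outputs accept a `reference_strand` flag so users who prefer the opposite
convention can flip it globally.

Gene annotation uses the standard rCRS coordinate table (13 protein genes,
22 tRNAs, 2 rRNAs, D-loop spanning 16024–576). Consequence calls translate
protein codons under the vertebrate mitochondrial genetic code (NCBI table
2, via Biopython) in the gene's frame and strand; genes ending mid-codon
(e.g. MT-ND1, MT-CO3) are completed with adenines, mirroring transcript
polyadenylation, and flagged. Where protein genes overlap (MT-ATP8/MT-ATP6,
MT-ND4L/MT-ND4) the first gene in genomic order determines the reported
class and the alternative consequence is kept in a diagnostic field, so
every substitution maps to exactly one of {D-loop, nonsynonymous,
synonymous, rRNA, tRNA, other-noncoding}. D-loop sub-regions (MT-OHR,
MT-CSB1–3, MT-LSP, MT-HSP1, MT-TAS) ship as a user-editable coordinate
table with standard literature values; lookups return the smallest
containing interval, so m.414 resolves to MT-LSP rather than the enclosing
MT-OHR.

### The bundled synthetic sequence

The true rCRS base string is not redistributed with the package. Instead,
`mitoshift.synthref` deterministically generates a composition-matched
synthetic stand-in (fixed internal seed, L-strand base frequencies
A/C/G/T ≈ 0.31/0.31/0.13/0.25) with homopolymer runs pinned at the six
low-complexity intervals, ATG start codons for the protein genes, and
reference alleles pinned at hotspot and pathogenic sites. Every
sequence-dependent computation (contexts, codons, opportunity ratios) is
exercised against this sequence through the same code paths a real rCRS
FASTA would take, and `load_reference` accepts a real FASTA. Results that
depend on the actual base identities of human mtDNA (e.g. the numeric NS/SS
opportunity ratio) are therefore illustrative on the bundled reference and
exact only with a real rCRS.

The bundled pathogenic-site table is a default list of well-established
confirmed pathogenic point mutations; substitute a curated list via
`load_reference(..., pathogenic_path=...)` for real analyses.

## Quality control

Variant-level filters run in a fixed order so per-rule removal counts are
reproducible: SNV-only → AF ≥ 2 % → depth ≥ 200× → ≥ 2 alt reads on each
strand → low-complexity exclusion → (bulk RNA only) removal of six known
mtRNA artefact sites. The strand rule is applied to the alt allele's
per-strand read counts, the only strand information in the call contract.
Heteroplasmy bands are 2–98 % for bulk and 2–95 % for single cells,
inclusive on the heteroplasmic side. The 2 % detection threshold reflects
the reproducibility limit of ~1000–2000× sequencing of mtDNA.

Sample QC fails lines with mean mtDNA depth < 400×, both members of any
pair sharing more than ten heteroplasmic variants at similar fractions
(|ΔHF| ≤ 0.05 by default — the similarity tolerance is a package choice,
exposed as a parameter), and iPSCs without a passing matched fibroblast.
Cell QC applies, in order: the 200× cell-depth rule, the ≥ 200× region
mask (from a per-site mean-depth table, when provided), the single-cell
heteroplasmy band, removal of stage-specific variants seen in exactly one
cell of a line, and exclusion of cells with more than 20 heteroplasmies.
Because the singleton rule precedes the cell rule, a cell is judged on its
corroborated variants only.

## Pair dynamics

With detection at threshold t = 0.02, a variant of a fibroblast→iPSC pair
is *shared* (≥ t in both, heteroplasmic in at least one member — a site
homoplasmic in both is a maternal haplotype marker, not a dynamic), *lost*
(heteroplasmic in the fibroblast, < t in the iPSC) or *iPSC-specific*
(≥ t in the iPSC, < t in the fibroblast). Donors with two derived lines
additionally get the five duo sub-categories. Partition identities
(shared + lost = fibroblast heteroplasmy set, etc.) are property-tested.

The heteroplasmic shift HS = log2(HF_iPSC/HF_fibro) is defined only for
shared variants; lost and specific variants keep their category labels
rather than receiving pseudo-counted shifts. HS > 6 is flagged as an
extreme increase. The direction excess is tested with an exact binomial
test against 0.5 and a two-sided Clopper–Pearson 95 % CI.

The iPSC-specific mutation rate is λ = k/(16,569·n_lines) per bp per
genome per reprogramming, where k counts specific variants after rescuing
those with any supporting fibroblast signal (AF > 0 in unfiltered calls)
as pre-existing; the 95 % CI is exact Poisson (χ² bounds). A per-molecule
rate requires an explicit copies-per-cell normaliser — it is never
inferred, because the cohort-average copy number is itself an estimate
(CN_mt = 2·DP_mt/DP_autosome). The threshold-sensitivity scan lowers only
the iPSC detection threshold in 0.5 % steps and is monotone by
construction.

Burden and mean-HF age models are OLS with age, sex and macro-haplogroup
(unordered categorical, most frequent level as reference); mean HF is
logit-transformed and clipped at 10⁻⁴. The shift-direction model is a
logistic regression of 1{HS > 0} on logit fibroblast HF, region (D-loop
reference level), haplogroup and age; complete separation (detected by
non-convergence or exploding standard errors) falls back to an
L2-penalised fit, flagged in the output metadata with standard errors
withheld rather than fabricated.

## Mutational signatures

Substitutions are pyrimidine-oriented: a purine reference base is
complemented together with its alt and trinucleotide context, and the
strand records where the pyrimidine sat. The 96-class spectrum reports
both raw counts and rates normalised by the trinucleotide context
frequencies of the circular reference on the corresponding strand;
the 6-class regional view reports relative frequencies. Collapsing 96 → 6
is exact by construction and tested as such.

Spectrum comparison runs one two-sided Fisher exact test per class
(class count vs remainder, cohort a vs cohort b) and combines the evidence
magnitudes z_i = Φ⁻¹(1 − p_i/2) with Stouffer's method,
Z = Σz_i/√k. The unsigned transform makes the combination a pure
divergence test: identical spectra (all p = 1) give Z = 0 and a combined
p of exactly 0.5, and classes diverging in opposite directions reinforce
rather than cancel. Direction per class is carried by the conditional-MLE
odds ratio and its CI. External signature correlation is a Pearson R² of
the strand-summed 96-class rate vector against each column of a
conventional context-labelled signature matrix, with a hard error on
label-order mismatch.

## Single-cell dynamics

Stages follow the day/pseudotime rules (mesendo: day 1–2, pseudotime
[0.15, 0.5); defendo: day 2–3, pseudotime > 0.7; [0.5, 0.7] undefined),
with boundary values assigned to the lower-labelled category and missing
pseudotime mapping to undefined — assignment is a total function.
Pseudo-bulk HF is the zero-inclusive mean over all cells of a group, so
pseudo-bulk = carrier proportion × carrier-mean HF whenever non-carriers
are exactly zero (tested as an identity). Carriers are cells with
HF ≥ 2 %, the bulk detection limit. Binned mutation frequencies divide
variant counts per carrier-proportion bin by cells × 16,569 bp.
Cross-stage concordance correlates log2 carrier proportions (variants
carried in both stages) and carrier-mean HFs for lines with ≥ 20 cells
per stage.

Lineage recovery drops variants carried by ≤ 1 % of a line's cells, then
clusters cells by Ward agglomerative clustering on the HF matrix with a
configurable dendrogram cut (default distance threshold 2.0 — within-clone
HF noise is ~0.02, so clone separations of order 1 dominate by orders of
magnitude); markers are the variants most elevated in each cluster. The
2-D display embedding (UMAP with a fixed recorded seed and the library's
default neighbourhood parameters, or PCA) is deliberately decoupled from
the clustering, which operates on the full HF matrix.

## Expression association

Variable genes are ranked by positive residual from a quadratic
mean–variance trend in log space — a deterministic overdispersion score.
Variance partitioning is an explicit OLS decomposition: categorical
factors (stage, batch, line) enter as dummy blocks and the mean
nonsynonymous HF as a continuous predictor; each factor's share is the
variance of its fitted component over the total, and the residual is
1 − R². For a single predictor this reduces to β²Var(x)/(β²Var(x)+σ²),
which the tests verify. The decomposition replaces heavier mixed-model
machinery deliberately: its calibration and recovery behaviour is what the
tests pin down, and components may covary, so shares are reported
individually rather than forced to sum to one.

Differential expression between mtDNA-genotype groups (carrier = HF ≥ 2 %,
moving to ≥ 50 % when the carrier median HF is near-homoplasmic so both
groups stay populated) is a per-gene OLS on log1p counts-per-10k with
stage covariates, t-tests on the genotype coefficient, and
Benjamini–Hochberg adjustment at FDR 0.1. Groups need ≥ 15 cells each.
CPM normalisation means strong one-sided expression shifts leak a small
compositional signal into other genes; the null-calibration test bounds
this at ≤ 2× the nominal rate.

## Synthetic cohort generator

The generator's defaults are the study conditions: 146 donors aged 27–77;
detectable heteroplasmy burden ~ Poisson(2.8 + 0.10·age) (slope 0.10/year;
intercept set so the mid-age mean burden is ~8); HF ~ Beta(0.5, 5)
truncated to the 2–98 % band (mean ≈ 9 %, modelling clonal expansion
implicitly through the HF distribution); a separate Poisson(3) pool of
sub-threshold variants with founding HFs from Beta(1, 30) truncated below
2 %, which powers the rescue and threshold-scan analyses; hotspots m.414G
at 19.2 % recurrence and m.2623G/m.13369C at 12.3 %; per-bp region
placement weights of 2.2 (D-loop), 1.6 (rRNA) and 1.0 elsewhere; 6-class ×
strand substitution weights dominated by C>T and T>C; reprogramming
bottleneck of N = 3 effective segregating units; de novo rate
8.6 × 10⁻⁵/bp/reprogramming with founding HFs Beta(1, 30) truncated at
2 %; read depth ~ Gamma(mean 1824, sd 500) with binomial alt sampling and
a fair binomial strand split; ~5 spurious single-strand error sites per
sample.

The bottleneck size deserves a note: nothing in the data model pins N, so
it was chosen by closed form — expected loss E[(1−p)^N] under the HF model
is ≈ 0.87/0.76/0.68 for N = 1/2/3 against an observed loss of ~84 % in
reprogramming cohorts, but N ≤ 2 collapses surviving fractions onto
{0.5, 1} and makes the shift distribution degenerate. N = 3 keeps the loss
heavy while preserving heteroplasmic diversity.

Single cells belong to latent clones (Dirichlet frequencies); a clone
carries each of its variants at a clone-level HF observed per cell with
Gaussian noise (sd 0.02, clipped to [0, 1]), stable across stages by
construction. Variants at HF > 0.5 are treated as ancestral and carried by
all clones. Expression is negative-binomial (dispersion 10) with a
log-link effect of the target variant's per-cell HF on a configurable set
of genes.

What the synthetic data does **not** emulate: linkage between variants on
molecules, cellular selection during reprogramming or culture, depth
heterogeneity along the genome (real scRNA coverage is strongly
gene-biased), UMI/ambient artefacts, or NUMT contamination. Passing tests
therefore demonstrate that the estimators recover the parameters of this
generative model at the study's sample sizes — they do not validate the
upstream variant calling, nor cohort-specific descriptive statistics
(mean burden 8 vs 3, mean HF 9.1 % vs 20.7 %, the published NS/SS ratios
and region frequencies), which require the real cohort; the formulas for
those quantities are exposed so they can be recomputed when real data are
supplied.

## Problem sizes and determinism

Tests and the acceptance script use cohorts of 20–146 donors, single-cell
matrices of 60–500 cells, and 50-replicate recovery loops — sizes at which
every recovery property has comfortable Monte-Carlo margins. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; the same seed reproduces byte-identical cohorts,
and pipeline reruns produce identical JSON summaries. Clustering is
invariant to cell order; UMAP runs single-threaded under a fixed
`random_state`.

## Known limitations

* Consequence calls at sites inside incomplete terminal codons depend on
  the polyadenylation-completion convention.
* The contamination check is pairwise and quadratic in samples; fine for
  cohorts of hundreds, not for biobanks.
* The variance decomposition attributes covarying components marginally;
  strongly confounded designs (stage nested in batch) will split shared
  variance arbitrarily between the factors involved.
* The DE test is a Gaussian approximation on log-normalised counts; for
  very low counts a count-model test would be better calibrated.
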