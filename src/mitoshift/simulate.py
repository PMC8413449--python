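"""Synthetic fibroblast–iPSC cohorts with the statistical structure the
analysis assumes.

The generator emulates, with explicit parameters:

* an age-dependent burden of clonally expanded fibroblast heteroplasmies
  (detectable count ~ Poisson(intercept + slope·age), slope defaulting to
  0.10 heteroplasmies/year),
* beta-distributed heteroplasmy fractions (clonal expansion is modelled by
  the HF distribution, not by explicit cell divisions),
* region-weighted mutation placement with recurrent hotspot injection
  (m.414G carried by ~19 % of lines by default),
* a binomial reprogramming bottleneck of N effective segregating units plus
  signature-driven de novo mutations at a Poisson genome rate,
* binomial read-sampling noise at configurable depth, split across strands,
* single cells with latent clone structure and variant-linked expression
  effects (negative-binomial counts, log link).

All functions are deterministic given ``params.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import MT_LENGTH, MitoReference, default_reference

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default 6-class × strand substitution probabilities (C>T / T>C dominant).
DEFAULT_SIGNATURE_WEIGHTS = {
    ("C>T", "L"): 0.25, ("C>T", "H"): 0.20,
    ("T>C", "L"): 0.15, ("T>C", "H"): 0.10,
    ("C>A", "L"): 0.08, ("C>A", "H"): 0.04,
    ("C>G", "L"): 0.03, ("C>G", "H"): 0.07,
    ("T>A", "L"): 0.03, ("T>A", "H"): 0.02,
    ("T>G", "L"): 0.02, ("T>G", "H"): 0.01,
}

#: Per-bp placement weight by feature kind (D-loop and rRNA enriched, as in
#: aged fibroblasts).
DEFAULT_REGION_WEIGHTS = {"dloop": 2.2, "rRNA": 1.6, "protein": 1.0,
                          "tRNA": 1.0, "noncoding": 1.0}

DEFAULT_HOTSPOTS = ((414, "G", 0.192), (2623, "G", 0.123), (13369, "C", 0.123))

_HAPLOGROUPS = ("H", "U", "J", "T", "K", "I", "V", "W", "X")
_HAPLOGROUP_PROBS = (0.45, 0.12, 0.11, 0.10, 0.08, 0.04, 0.04, 0.03, 0.03)

TRUTH_COLUMNS = ["sample_id", "donor_id", "position", "ref", "alt",
                 "true_hf", "origin"]


@dataclass
class SimulationParams:
    """Study-condition defaults for the synthetic cohort."""

    n_donors: int = 146
    age_range: tuple[int, int] = (27, 77)
    burden_slope: float = 0.10        # detectable heteroplasmies per year
    burden_intercept: float = 2.8     # gives a mean burden of ~8 at mid-age
    subthreshold_burden: float = 3.0  # mean count of HF<2% variants per line
    hf_distribution: tuple[float, float] = (0.5, 5.0)  # beta, mean HF ≈ 9 %
    region_weights: dict = field(default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    hotspot_sites: tuple = DEFAULT_HOTSPOTS
    bottleneck_size: int = 3          # effective segregating units N
    de_novo_rate: float = 8.6e-5      # new mutations / bp / reprogramming
    founding_hf_beta: tuple[float, float] = (1.0, 30.0)  # truncated at 2 %
    signature_weights: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_WEIGHTS))
    depth_mean: float = 1824.0
    depth_sd: float = 500.0
    error_sites_per_sample: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.de_novo_rate < 0:
            raise ValueError("de_novo_rate must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be a non-degenerate interval")
        total = sum(self.signature_weights.values())
        if not np.isclose(total, 1.0):
            self.signature_weights = {k: v / total
                                      for k, v in self.signature_weights.items()}

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# -- signature-aware variant placement ----------------------------------------


def _placement_tables(ref: MitoReference, region_weights: dict):
    """Per-base position lists and region weights, cached on the reference."""
    key = "_mitoshift_placement"
    cached = getattr(ref, key, None)
    if cached is not None and cached[0] == tuple(sorted(region_weights.items())):
        return cached[1], cached[2]
    positions_by_base: dict[str, np.ndarray] = {}
    weights = np.ones(MT_LENGTH)
    seq = ref.sequence
    for pos in range(1, MT_LENGTH + 1):
        weights[pos - 1] = region_weights.get(ref.feature_kind(pos), 1.0)
    for b in "ACGT":
        positions_by_base[b] = np.array(
            [i + 1 for i in range(MT_LENGTH) if seq[i] == b])
    setattr(ref, key, (tuple(sorted(region_weights.items())),
                       positions_by_base, weights))
    return positions_by_base, weights


def sample_signature_variants(ref: MitoReference, n: int,
                              signature_weights: dict, region_weights: dict,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Draw n substitutions with exact 6-class×strand frequencies.

    The (class, strand) label is drawn from ``signature_weights``; the
    position is then drawn among reference positions whose base matches that
    label, weighted by region.  A pyrimidine class on strand L needs the
    FASTA base itself; on strand H it needs the complement.
    """
    pos_by_base, region_w = _placement_tables(ref, region_weights)
    classes = list(signature_weights)
    probs = np.array([signature_weights[c] for c in classes])
    idx = rng.choice(len(classes), size=n, p=probs)
    rows = []
    for i in idx:
        cls, strand = classes[i]
        pyr, alt_pyr = cls[0], cls[2]
        if strand == "L":
            ref_base, alt = pyr, alt_pyr
        else:
            ref_base, alt = _COMP[pyr], _COMP[alt_pyr]
        candidates = pos_by_base[ref_base]
        w = region_w[candidates - 1]
        pos = int(rng.choice(candidates, p=w / w.sum()))
        rows.append((pos, ref_base, alt, cls, strand))
    return pd.DataFrame(rows, columns=["position", "ref", "alt",
                                       "substitution_class", "strand"])


def _truncated_beta(rng, a, b, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


# -- fibroblast cohort ---------------------------------------------------------


def simulate_fibroblast_cohort(params: SimulationParams,
                               ref: MitoReference | None = None,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate donor fibroblast lines and their true heteroplasmies.

    Per donor, the number of detectable (HF ≥ 2 %) clonally expanded
    heteroplasmies is Poisson(intercept + slope·age); their HFs follow the
    beta model truncated to the 2–98 % band.  A separate Poisson pool of
    sub-threshold (HF < 2 %) variants supports rescue and threshold-scan
    analyses.  Hotspot sites are injected with their recurrence
    probabilities.
    """
    ref = ref or default_reference()
    rng = params.rng(salt=1)
    lo, hi = params.age_range
    ages = rng.integers(lo, hi + 1, size=params.n_donors)
    sexes = rng.choice(["F", "M"], size=params.n_donors, p=[0.55, 0.45])
    haps = rng.choice(_HAPLOGROUPS, size=params.n_donors, p=_HAPLOGROUP_PROBS)
    a, b = params.hf_distribution
    fa, fb = params.founding_hf_beta

    samples, truth = [], []
    for d in range(params.n_donors):
        donor = f"D{d:03d}"
        line = f"{donor}-fibro"
        samples.append({
            "line_id": line, "donor_id": donor, "tissue": "fibroblast",
            "age": int(ages[d]), "sex": sexes[d], "macro_haplogroup": haps[d],
            "passage": int(rng.integers(2, 8)),
            "mean_mtdna_depth": float(rng.normal(params.depth_mean,
                                                 params.depth_sd / 4)),
            "mean_autosomal_depth": float(rng.normal(44, 9)),
        })
        carried: set[int] = set()

        for pos, alt, p_carrier in params.hotspot_sites:
            if rng.random() < p_carrier:
                hf = float(_truncated_beta(rng, a, b, 0.02, 0.98, 1)[0])
                truth.append((line, donor, pos, ref.base(pos), alt, hf,
                              "somatic_fibroblast"))
                carried.add(pos)

        n_det = rng.poisson(params.burden_intercept
                            + params.burden_slope * ages[d])
        n_det = max(0, n_det - len(carried))
        det = sample_signature_variants(ref, int(n_det),
                                        params.signature_weights,
                                        params.region_weights, rng)
        hfs = _truncated_beta(rng, a, b, 0.02, 0.98, len(det))
        for (_, r), hf in zip(det.iterrows(), hfs):
            if r["position"] in carried:
                continue
            carried.add(r["position"])
            truth.append((line, donor, int(r["position"]), r["ref"], r["alt"],
                          float(hf), "somatic_fibroblast"))

        n_sub = rng.poisson(params.subthreshold_burden)
        sub = sample_signature_variants(ref, int(n_sub),
                                        params.signature_weights,
                                        params.region_weights, rng)
        sub_hfs = _truncated_beta(rng, fa, fb, 1e-4, 0.02, len(sub))
        for (_, r), hf in zip(sub.iterrows(), sub_hfs):
            if r["position"] in carried:
                continue
            carried.add(r["position"])
            truth.append((line, donor, int(r["position"]), r["ref"], r["alt"],
                          float(hf), "somatic_fibroblast"))

    return (pd.DataFrame(samples),
            pd.DataFrame(truth, columns=TRUTH_COLUMNS))


# -- reprogramming bottleneck --------------------------------------------------


def bottleneck(hf: np.ndarray, n_units: int,
               rng: np.random.Generator) -> np.ndarray:
    """One binomial bottleneck: p' = B/N with B ~ Binomial(N, p).

    Unbiased (E[p'] = p) with Var(p') = p(1-p)/N; N = 1 forces fixation or
    loss.
    """
    return rng.binomial(n_units, np.asarray(hf, dtype=float)) / n_units


def simulate_reprogramming(samples: pd.DataFrame, truth: pd.DataFrame,
                           params: SimulationParams,
                           n_ipsc_per_donor: dict | int = 1,
                           ref: MitoReference | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive iPSC lines from fibroblast truth through the bottleneck.

    Each fibroblast heteroplasmy is resampled independently per iPSC line
    through a Binomial(N, p) bottleneck; de novo mutations are added as
    Poisson(de_novo_rate × 16,569) events per line with signature-weighted
    substitution types and low founding HFs.
    """
    ref = ref or default_reference()
    rng = params.rng(salt=2)
    fa, fb = params.founding_hf_beta
    fibros = samples[samples["tissue"] == "fibroblast"]
    ipsc_samples, ipsc_truth = [], []
    for _, fs in fibros.iterrows():
        donor = fs["donor_id"]
        n_lines = (n_ipsc_per_donor.get(donor, 0)
                   if isinstance(n_ipsc_per_donor, dict) else n_ipsc_per_donor)
        fib_vars = truth[truth["sample_id"] == fs["line_id"]]
        for k in range(n_lines):
            line = f"{donor}-ipsc{k + 1}"
            ipsc_samples.append({
                "line_id": line, "donor_id": donor, "tissue": "iPSC",
                "age": fs["age"], "sex": fs["sex"],
                "macro_haplogroup": fs["macro_haplogroup"],
                "passage": int(rng.integers(8, 44)),
                "mean_mtdna_depth": float(rng.normal(params.depth_mean,
                                                     params.depth_sd / 4)),
                "mean_autosomal_depth": float(rng.normal(44, 9)),
            })
            if len(fib_vars):
                post = bottleneck(fib_vars["true_hf"].to_numpy(),
                                  params.bottleneck_size, rng)
                for (_, r), hf in zip(fib_vars.iterrows(), post):
                    if hf > 0:
                        ipsc_truth.append((line, donor, r["position"], r["ref"],
                                           r["alt"], float(hf), r["origin"]))
            n_new = rng.poisson(params.de_novo_rate * MT_LENGTH)
            new = sample_signature_variants(ref, int(n_new),
                                            params.signature_weights,
                                            params.region_weights, rng)
            if len(new):
                hfs = _truncated_beta(rng, fa, fb, 0.02, 0.98, len(new))
                taken = set(fib_vars["position"])
                for (_, r), hf in zip(new.iterrows(), hfs):
                    if r["position"] in taken:
                        continue
                    taken.add(r["position"])
                    ipsc_truth.append((line, donor, int(r["position"]),
                                       r["ref"], r["alt"], float(hf),
                                       "de_novo_reprogramming"))
    return (pd.DataFrame(ipsc_samples),
            pd.DataFrame(ipsc_truth, columns=TRUTH_COLUMNS))


# -- read-level noise ----------------------------------------------------------


def simulate_read_counts(truth: pd.DataFrame, params: SimulationParams,
                         source: str = "wgs_bulk",
                         ref: MitoReference | None = None) -> pd.DataFrame:
    """Observed variant calls: binomial read sampling at gamma-distributed depth.

    Alt reads ~ Binomial(depth, true HF), split binomially across strands;
    spurious single-strand error calls are added per sample to exercise the
    strand filter.  Sites whose sampled alt count is zero are not emitted.
    """
    ref = ref or default_reference()
    rng = params.rng(salt=3)
    shape = (params.depth_mean / params.depth_sd) ** 2
    scale = params.depth_sd ** 2 / params.depth_mean
    rows = []
    for _, r in truth.iterrows():
        depth = max(1, int(round(rng.gamma(shape, scale))))
        alt = rng.binomial(depth, min(1.0, r["true_hf"]))
        if alt == 0:
            continue
        fwd = rng.binomial(alt, 0.5)
        rows.append((r["sample_id"], int(r["position"]), r["ref"], r["alt"],
                     alt / depth, depth, int(fwd), int(alt - fwd), source))
    for sample in truth["sample_id"].unique():
        for _ in range(rng.poisson(params.error_sites_per_sample)):
            pos = int(rng.integers(1, MT_LENGTH + 1))
            base = ref.base(pos)
            alt = rng.choice([b for b in "ACGT" if b != base])
            depth = max(1, int(round(rng.gamma(shape, scale))))
            n_err = int(rng.integers(1, 4))  # 1-3 reads, one strand only
            strand = rng.random() < 0.5
            rows.append((sample, pos, base, alt, n_err / depth, depth,
                         n_err if strand else 0, 0 if strand else n_err,
                         source))
    return pd.DataFrame(rows, columns=["sample_id", "position", "ref", "alt",
                                       "allele_fraction", "depth",
                                       "alt_forward", "alt_reverse", "source"])


# -- single cells --------------------------------------------------------------

_STAGE_RULES = {
    "iPSC": ((0,), (0.0, 0.15)),
    "mesendo": ((1, 2), (0.15, 0.5)),
    "defendo": ((2, 3), (0.7, 1.0)),
    "undefined": ((2,), (0.5, 0.7)),
}


def simulate_single_cells(line_truth: pd.DataFrame, n_cells: int,
                          stages: tuple = ("iPSC", "mesendo", "defendo"),
                          params: SimulationParams | None = None, *,
                          n_clones: int = 3,
                          clone_frequencies: np.ndarray | None = None,
                          clone_hf: pd.DataFrame | None = None,
                          hf_noise_sd: float = 0.02,
                          n_genes: int = 100, n_affected_genes: int = 5,
                          expression_effect: float = 1.0,
                          target_variant: str | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Single cells of one line with latent clone structure.

    Cells belong to latent clones; a clone carries each of its variants at a
    clone-level HF (stable across stages), observed per cell with small
    Gaussian noise.  Expression counts are negative-binomial with log-mean
    shifted by ``expression_effect`` × HF of the target variant for the
    affected genes.  Pass ``clone_hf`` (clones × variants HF matrix) to pin
    the clone structure exactly; otherwise each truth variant is assigned to
    one random clone at its truth HF (variants at HF > 0.5 are treated as
    ancestral and carried by every clone).
    """
    params = params or SimulationParams()
    rng = params.rng(salt=4)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    if clone_hf is None:
        names = [f"{int(r.position)}{r.ref}>{r.alt}"
                 for r in line_truth.itertuples()]
        clone_hf = pd.DataFrame(0.0, index=range(n_clones), columns=names)
        for name, (_, r) in zip(names, line_truth.iterrows()):
            if r["true_hf"] > 0.5:
                clone_hf.loc[:, name] = r["true_hf"]
            else:
                clone_hf.loc[int(rng.integers(n_clones)), name] = r["true_hf"]
    n_clones = len(clone_hf)
    if clone_frequencies is None:
        clone_frequencies = rng.dirichlet(np.full(n_clones, 2.0))
    clone_frequencies = np.asarray(clone_frequencies, dtype=float)
    clone_frequencies = clone_frequencies / clone_frequencies.sum()

    clone_of = rng.choice(n_clones, size=n_cells, p=clone_frequencies)
    stage_of = [stages[i % len(stages)] for i in range(n_cells)]
    rng.shuffle(stage_of)

    hf = clone_hf.to_numpy()[clone_of]
    noise = rng.normal(0, hf_noise_sd, size=hf.shape)
    hf = np.where(hf > 0, np.clip(hf + noise, 0, 1), 0.0)
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    cell_hf = pd.DataFrame(hf, index=cells, columns=clone_hf.columns)

    meta_rows = []
    for c, st, cl in zip(cells, stage_of, clone_of):
        days, (p_lo, p_hi) = _STAGE_RULES[st]
        meta_rows.append({
            "cell_id": c, "stage_true": st, "clone": int(cl),
            "collection_day": int(rng.choice(days)),
            "pseudotime": float(rng.uniform(p_lo, p_hi)),
        })
    meta = pd.DataFrame(meta_rows)

    if target_variant is None and len(cell_hf.columns):
        target_variant = cell_hf.var().idxmax()
    target = (cell_hf[target_variant].to_numpy()
              if target_variant is not None else np.zeros(n_cells))
    base_mean = rng.lognormal(mean=1.5, sigma=0.8, size=n_genes)
    affected = rng.choice(n_genes, size=min(n_affected_genes, n_genes),
                          replace=False)
    log_mu = np.log(base_mean)[None, :].repeat(n_cells, axis=0)
    log_mu[:, affected] += expression_effect * target[:, None]
    mu = np.exp(log_mu)
    r_disp = 10.0
    counts = rng.negative_binomial(r_disp, r_disp / (r_disp + mu))
    expr = pd.DataFrame(counts, index=cells,
                        columns=[f"gene{g:03d}" for g in range(n_genes)])
    meta["affected_genes"] = [",".join(f"gene{g:03d}" for g in sorted(affected))] * n_cells
    meta["target_variant"] = target_variant
    return cell_hf, expr, meta
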