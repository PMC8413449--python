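"""Pair classification, shifts, rates, selection and regression models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoshift import dynamics as dyn
from mitoshift.reference import MT_LENGTH
from mitoshift.simulate import (SimulationParams, simulate_fibroblast_cohort,
                                simulate_reprogramming)
from tests.conftest import calls_frame, make_call


def _samples(n_two=58, n_one=25, n_fibro_only=63):
    rows = []
    donor = 0
    for n_ipsc, count in ((2, n_two), (1, n_one), (0, n_fibro_only)):
        for _ in range(count):
            d = f"D{donor:03d}"
            rows.append({"line_id": f"{d}-f", "donor_id": d,
                         "tissue": "fibroblast"})
            for k in range(n_ipsc):
                rows.append({"line_id": f"{d}-i{k}", "donor_id": d,
                             "tissue": "iPSC"})
            donor += 1
    return pd.DataFrame(rows)


class TestPairing:
    def test_cohort_pair_count(self):
        """58 donors with two iPSCs + 25 with one → 141 pairs from 146
        fibroblasts."""
        samples = _samples()
        assert (samples["tissue"] == "fibroblast").sum() == 146
        pairs = dyn.pair_lines(samples)
        assert len(pairs) == 141

    def test_two_ipscs_share_one_fibroblast(self):
        pairs = dyn.pair_lines(_samples(n_two=1, n_one=0, n_fibro_only=0))
        assert len(pairs) == 2
        assert pairs[0][0] == pairs[1][0]

    def test_empty_and_orphan(self):
        assert dyn.pair_lines(pd.DataFrame(columns=["line_id", "donor_id",
                                                    "tissue"])) == []
        orphan = pd.DataFrame([{"line_id": "I", "donor_id": "D",
                                "tissue": "iPSC"}])
        assert dyn.pair_lines(orphan) == []


def _call(sample, pos, af, ref=None):
    return make_call(sample_id=sample, position=pos, allele_fraction=af,
                     reference=ref)


class TestClassification:
    def test_shared_lost_specific_definitions(self, ref):
        fibro = calls_frame([_call("F", 1000, 0.10, ref),
                             _call("F", 2000, 0.10, ref)])
        ipsc = calls_frame([_call("I", 1000, 0.30, ref),
                            _call("I", 3000, 0.20, ref)])
        out = dyn.classify_pair(("F", "I"), fibro, ipsc, ref)
        cats = out.set_index("position")["category"]
        assert cats[1000] == "shared"
        assert cats[2000] == "lost"
        assert cats[3000] == "ipsc_specific"

    def test_homoplasmic_in_both_is_not_a_dynamic(self, ref):
        fibro = calls_frame([_call("F", 1000, 1.0, ref)])
        ipsc = calls_frame([_call("I", 1000, 1.0, ref)])
        out = dyn.classify_pair(("F", "I"), fibro, ipsc, ref)
        assert len(out) == 0

    def test_partition_laws_on_simulated_cohort(self, ref):
        """shared+lost exhausts the fibroblast heteroplasmy set and
        shared+specific the iPSC variant set."""
        params = SimulationParams(seed=17, n_donors=20)
        fs, ft = simulate_fibroblast_cohort(params, ref)
        iss, ist = simulate_reprogramming(fs, ft, params, 1, ref)
        t = 0.02
        for donor in fs["donor_id"][:10]:
            fl, il = f"{donor}-fibro", f"{donor}-ipsc1"
            fibro = ft[ft["sample_id"] == fl].rename(
                columns={"true_hf": "allele_fraction"})
            ipsc = ist[ist["sample_id"] == il].rename(
                columns={"true_hf": "allele_fraction"})
            out = dyn.classify_pair((fl, il), fibro, ipsc)
            if len(out) == 0:
                continue
            het_f = set(fibro[(fibro["allele_fraction"] >= t)
                              & (fibro["allele_fraction"] <= 0.98)]["position"])
            got_fib = set(out[out["category"].isin(["shared", "lost"])]
                          ["position"])
            assert het_f <= got_fib | set(
                out[out["category"] == "shared"]["position"])
            spec = set(out[out["category"] == "ipsc_specific"]["position"])
            in_i = set(ipsc[ipsc["allele_fraction"] >= t]["position"])
            assert spec <= in_i
            assert spec.isdisjoint(
                set(fibro[fibro["allele_fraction"] >= t]["position"]))

    def test_duo_subcategories(self, ref):
        fibro = calls_frame([_call("F", 1000, 0.10, ref),
                             _call("F", 2000, 0.10, ref),
                             _call("F", 3000, 0.10, ref)])
        i1 = calls_frame([_call("I1", 1000, 0.30, ref),
                          _call("I1", 2000, 0.30, ref),
                          _call("I1", 4000, 0.30, ref),
                          _call("I1", 5000, 0.30, ref)])
        i2 = calls_frame([_call("I2", 1000, 0.40, ref),
                          _call("I2", 4000, 0.20, ref)])
        out = dyn.classify_duo(fibro, i1, i2, ("F", "I1", "I2"))
        sub = out.set_index("position")["duo_subcategory"]
        assert sub[1000] == "shared_both"
        assert sub[2000] == "shared_one"
        assert sub[3000] == "lost_both"
        assert sub[4000] == "ipsc_specific_both"
        assert sub[5000] == "ipsc_specific_one"
        # both unique-variant sets partition completely
        fib_side = sub.isin(["shared_both", "shared_one", "lost_both"])
        assert set(sub[fib_side].index) == {1000, 2000, 3000}
        assert set(sub[~fib_side].index) == {4000, 5000}


class TestHeteroplasmicShift:
    def test_worked_doubling_case(self):
        assert dyn.heteroplasmic_shift(0.02, 0.04) == pytest.approx(1.0)

    def test_identity_and_octupling(self):
        for x in (0.02, 0.3, 0.9):
            assert dyn.heteroplasmic_shift(x, x) == 0.0
        assert dyn.heteroplasmic_shift(0.10, 0.80) == pytest.approx(3.0)

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.uniform(0.02, 0.98, 2)
            assert dyn.heteroplasmic_shift(a, b) == pytest.approx(
                -dyn.heteroplasmic_shift(b, a))
            c = rng.uniform(0.1, 1.0)
            assert dyn.heteroplasmic_shift(a * c, b * c) == pytest.approx(
                dyn.heteroplasmic_shift(a, b))

    def test_zero_hf_rejected(self):
        with pytest.raises(ValueError):
            dyn.heteroplasmic_shift(0.0, 0.5)

    def test_shift_records_direction_and_extreme_flags(self, ref):
        classified = pd.DataFrame([
            {"fibroblast_line": "F", "ipsc_line": "I", "position": 1000,
             "ref": "A", "alt": "G", "hf_fibro": 0.02,
             "hf_ipsc": 0.04, "category": "shared", "region": "dloop"},
            {"fibroblast_line": "F", "ipsc_line": "I", "position": 2000,
             "ref": "A", "alt": "G", "hf_fibro": 0.01, "hf_ipsc": 0.9,
             "category": "shared", "region": "dloop"},
            {"fibroblast_line": "F", "ipsc_line": "I", "position": 3000,
             "ref": "A", "alt": "G", "hf_fibro": 0.5, "hf_ipsc": 0.25,
             "category": "shared", "region": "dloop"},
        ])
        rec = dyn.shift_records(classified)
        assert list(rec["direction"]) == ["increase", "increase", "decrease"]
        assert list(rec["extreme"]) == [False, True, False]  # log2(90) > 6


class TestDirectionBinomial:
    def test_reported_direction_ci(self):
        """138 of 161 shared variants increasing gives the 0.793–0.907 CI."""
        p, lo, hi = dyn.direction_binomial(138, 161)
        assert round(lo, 3) == 0.793
        assert round(hi, 3) == 0.907
        assert p < 1e-15

    def test_boundary_cases_match_clopper_pearson_closed_form(self):
        _, lo, hi = dyn.direction_binomial(0, 20)
        assert lo == 0.0
        _, lo8, _ = dyn.direction_binomial(8, 8)
        assert lo8 == pytest.approx(0.025 ** (1 / 8), abs=1e-9)

    def test_ci_matches_beta_quantile_oracle(self):
        for k, n in ((3, 17), (10, 33), (25, 40)):
            _, lo, hi = dyn.direction_binomial(k, n)
            assert lo == pytest.approx(stats.beta.ppf(0.025, k, n - k + 1),
                                       abs=1e-9)
            assert hi == pytest.approx(stats.beta.ppf(0.975, k + 1, n - k),
                                       abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dyn.direction_binomial(0, 0)


def _classified(n_specific, n_lines=1, pathogenic=None):
    rows = []
    for i in range(n_specific):
        rows.append({"fibroblast_line": f"F{i % n_lines}",
                     "ipsc_line": f"I{i % n_lines}",
                     "position": 1000 + i, "ref": "A", "alt": "G",
                     "hf_fibro": 0.0, "hf_ipsc": 0.3,
                     "category": "ipsc_specific",
                     "pathogenic": bool(pathogenic and i in pathogenic)})
    return pd.DataFrame(rows, columns=["fibroblast_line", "ipsc_line",
                                       "position", "ref", "alt", "hf_fibro",
                                       "hf_ipsc", "category", "pathogenic"])


class TestMutationRate:
    def test_pathogenic_rate_arithmetic(self):
        """5 pathogenic events across 141 lines → 2.14e-6 /bp/genome."""
        cl = _classified(5, pathogenic=range(5))
        est = dyn.specific_mutation_rate(cl, 141, pathogenic_only=True)
        assert est.rate_per_bp_per_genome == pytest.approx(2.14e-6,
                                                           rel=5e-3)

    def test_toy_rate_arithmetic(self):
        est = dyn.specific_mutation_rate(_classified(3), 2)
        assert est.rate_per_bp_per_genome == pytest.approx(9.05e-5, rel=1e-2)

    def test_zero_events_poisson_upper_bound(self):
        est = dyn.specific_mutation_rate(_classified(0), 10)
        assert est.rate_per_bp_per_genome == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high == pytest.approx(3.689 / (MT_LENGTH * 10),
                                            rel=1e-3)

    def test_rate_scales_inversely_with_lines_and_ignores_order(self):
        cl = _classified(12, n_lines=4)
        a = dyn.specific_mutation_rate(cl, 4)
        b = dyn.specific_mutation_rate(cl.sample(frac=1, random_state=0), 4)
        c = dyn.specific_mutation_rate(cl, 8)
        assert a.rate_per_bp_per_genome == b.rate_per_bp_per_genome
        assert a.rate_per_bp_per_genome == pytest.approx(
            2 * c.rate_per_bp_per_genome)

    def test_subthreshold_fibroblast_signal_rescues_events(self):
        cl = _classified(10)
        raw = calls_frame([make_call(sample_id="F0", position=1000 + i,
                                     allele_fraction=0.005, depth=2000)
                           for i in range(3)])
        est = dyn.specific_mutation_rate(cl, 5, fibro_calls_unfiltered=raw)
        assert est.n_rescued == 3
        assert est.n_events == 7

    def test_ci_contains_point_estimate(self):
        est = dyn.specific_mutation_rate(_classified(7), 3)
        assert est.ci_low <= est.rate_per_bp_per_genome <= est.ci_high


class TestThresholdSensitivity:
    def test_rate_monotone_as_threshold_falls(self, ref):
        rng = np.random.default_rng(3)
        rows = [make_call(sample_id="I0", position=int(p),
                          allele_fraction=float(af), reference=ref)
                for p, af in zip(rng.integers(600, 16000, 200),
                                 rng.uniform(0.001, 0.5, 200))]
        ipsc = calls_frame(rows)
        fibro = calls_frame([make_call(sample_id="F0", position=700,
                                       allele_fraction=0.001, reference=ref)])
        out = dyn.threshold_sensitivity([("F0", "I0")], fibro, ipsc)
        rates = out.sort_values("threshold", ascending=False)[
            "rate_per_bp_per_genome"].to_numpy()
        assert (np.diff(rates) >= 0).all()

    def test_uniform_founding_hfs_double_rate_at_half_threshold(self, ref):
        """With founding HFs uniform on (0, 3%), halving the detection
        threshold from 2% to 1% doubles the detected event count
        (closed form: P(U ≥ 0.01)/P(U ≥ 0.02) = 2 for U(0, 0.03))."""
        n = 4000
        rng = np.random.default_rng(5)
        positions = rng.choice(np.arange(600, 16000), size=n, replace=False)
        rows = [make_call(sample_id="I0", position=int(p),
                          allele_fraction=float(af), reference=ref)
                for p, af in zip(positions, rng.uniform(0, 0.03, n))]
        ipsc = calls_frame(rows)
        fibro = calls_frame([]).reindex(columns=ipsc.columns)
        out = dyn.threshold_sensitivity([("F0", "I0")], fibro, ipsc,
                                        thresholds=(0.02, 0.01)).set_index(
            "threshold")
        ratio = (out.loc[0.01, "n_events"] / out.loc[0.02, "n_events"])
        assert ratio == pytest.approx(2.0, abs=0.15)


class TestSelectionAndRegions:
    def test_nsss_ratio_arithmetic(self):
        df = pd.DataFrame({"region": ["nonsynonymous"] * 4 + ["synonymous"]})
        assert dyn.nsss_ratio(df) == 4.0
        assert dyn.nsss_ratio(pd.DataFrame({"region": ["synonymous"]})) == 0.0
        assert dyn.nsss_ratio(pd.DataFrame({"region": ["nonsynonymous"]})) is None

    def test_uniform_substitutions_match_opportunity_ratio(self, ref):
        """Classifying every possible coding substitution reproduces the
        genome's NS/SS opportunity ratio by construction."""
        opp = dyn.coding_opportunity_ratio(ref)
        assert 2.0 < opp < 12.0
        rows = []
        for g in ref.genes:
            if g.kind != "protein" or g.name != "MT-ND3":
                continue
            for pos in range(g.start, g.end + 1):
                base = ref.base(pos)
                for alt in "ACGT":
                    if alt != base:
                        rows.append({"region": ref.classify_variant_region(
                            pos, base, alt).value})
        ratio = dyn.nsss_ratio(pd.DataFrame(rows))
        ns = sum(r["region"] == "nonsynonymous" for r in rows)
        ss = sum(r["region"] == "synonymous" for r in rows)
        assert ratio == pytest.approx(ns / ss)

    def test_region_frequency_arithmetic(self, ref):
        variants = pd.DataFrame({"position": [100] * 10})  # D-loop sites
        out = dyn.region_mutation_frequency(variants, ref, 10).set_index(
            "region")
        assert out.loc["dloop", "frequency_per_bp"] == pytest.approx(
            10 / (1122 * 10))

    def test_uniform_placement_shows_no_enrichment(self, ref):
        rng = np.random.default_rng(11)
        variants = pd.DataFrame(
            {"position": rng.integers(1, MT_LENGTH + 1, 300)})
        out = dyn.region_mutation_frequency(variants, ref, 50)
        big = out[out["length_bp"] > 1000]
        assert (big["fisher_vs_rest_p"] > 0.01).all()

    def test_fisher_matches_hypergeometric_oracle(self):
        a, la, b, lb = 7, 100, 3, 200
        _, p = stats.fisher_exact([[a, la - a], [b, lb - b]])
        # brute-force hypergeometric enumeration
        total_k, total_n = a + b, la + lb
        pmf = [stats.hypergeom.pmf(k, total_n, total_k, la)
               for k in range(total_k + 1)]
        p_obs = pmf[a]
        p_oracle = sum(x for x in pmf if x <= p_obs + 1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-9)


class TestCopyNumber:
    def test_identity_and_cohort_means(self):
        assert dyn.relative_copy_number(44.0, 44.0) == 2.0
        assert dyn.relative_copy_number(1824.0, 44.0) == pytest.approx(82.9,
                                                                       abs=0.1)
        assert dyn.relative_copy_number(0.0, 44.0) == 0.0

    def test_zero_autosomal_depth_rejected(self):
        with pytest.raises(ValueError):
            dyn.relative_copy_number(1000.0, 0.0)


class TestAgeModels:
    def test_slope_recovery_on_simulated_cohort(self, ref):
        params = SimulationParams(seed=23, n_donors=146)
        samples, truth = simulate_fibroblast_cohort(params, ref)
        det = truth[truth["true_hf"] >= 0.02]
        burden = det.groupby("sample_id").size()
        mean_hf = det.groupby("sample_id")["true_hf"].mean()
        models = dyn.fit_age_models(samples, burden, mean_hf)
        fit = models["burden_fibroblast"]
        assert abs(fit.loc["age", "estimate"] - 0.10) <= 2 * fit.loc["age",
                                                                     "se"]

    def test_shuffled_ages_give_null_slope(self, ref):
        params = SimulationParams(seed=29, n_donors=146)
        samples, truth = simulate_fibroblast_cohort(params, ref)
        det = truth[truth["true_hf"] >= 0.02]
        burden = det.groupby("sample_id").size()
        mean_hf = det.groupby("sample_id")["true_hf"].mean()
        rng = np.random.default_rng(0)
        samples = samples.assign(age=rng.permutation(samples["age"].to_numpy()))
        fit = dyn.fit_age_models(samples, burden, mean_hf)[
            "burden_fibroblast"]
        est, se = fit.loc["age", "estimate"], fit.loc["age", "se"]
        assert abs(est) <= 2.5 * se


def _shift_frame(n, beta_nonsyn=0.78, seed=0):
    rng = np.random.default_rng(seed)
    regions = rng.choice(["dloop", "nonsynonymous", "synonymous", "tRNA",
                          "rRNA"], size=n)
    hf = rng.uniform(0.02, 0.6, n)
    logit = np.log(hf / (1 - hf))
    age = rng.integers(27, 78, n)
    eta = 0.3 + beta_nonsyn * (regions == "nonsynonymous")
    s = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame({
        "region": regions, "hf_fibro_logit": logit, "age": age,
        "haplogroup": rng.choice(["H", "U", "J"], n),
        "hs": np.where(s, 1.0, -1.0),
        "direction": np.where(s, "increase", "decrease")})


class TestShiftDirectionModel:
    def test_region_coefficient_recovery(self):
        """The +0.78 nonsynonymous-vs-D-loop log-odds is recovered."""
        fit = dyn.fit_shift_direction_model(_shift_frame(1500, seed=3))
        key = [i for i in fit.index if "nonsynonymous" in i][0]
        est, se = fit.loc[key, "estimate"], fit.loc[key, "se"]
        assert abs(est - 0.78) <= 2 * se
        assert not fit.attrs["separation"]

    def test_balanced_covariate_free_data_gives_null_intercept(self):
        df = _shift_frame(2000, beta_nonsyn=0.0, seed=5)
        df["hs"] = np.resize([1.0, -1.0], len(df))
        df["direction"] = np.where(df["hs"] > 0, "increase", "decrease")
        fit = dyn.fit_shift_direction_model(df)
        est, se = fit.loc["Intercept", "estimate"], fit.loc["Intercept", "se"]
        assert abs(est) <= 2.5 * se

    def test_all_increases_raises_separation_flag(self):
        df = _shift_frame(100, seed=7)
        df["hs"] = 1.0
        df["direction"] = "increase"
        fit = dyn.fit_shift_direction_model(df)
        assert fit.attrs["separation"]
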