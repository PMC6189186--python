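"""Hard filters, beta-binomial error models, BH correction and SRM/MRM
classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainmosaic.synthetic_study import (StudyConfig, generate_study,
                                         spike_in_mixture)
from brainmosaic.variant_screen import (ScreenConfig, SiteErrorModel,
                                        bh_adjust, classify_variants,
                                        detect_spike_ins,
                                        fit_site_error_model, hard_filter,
                                        screen_performance, site_pvalue)

CFG = ScreenConfig()


def _row(depth_fwd=600, depth_rev=600, alt_fwd=10, alt_rev=10,
         population_maf=0.0, repeat_flag=0):
    return {"depth_fwd": depth_fwd, "depth_rev": depth_rev,
            "alt_fwd": alt_fwd, "alt_rev": alt_rev,
            "population_maf": population_maf, "repeat_flag": repeat_flag}


class TestHardFilter:
    def test_depth_boundary(self):
        assert "depth" in hard_filter(_row(499, 500, 10, 10), CFG)
        assert hard_filter(_row(500, 500, 6, 4), CFG) == []

    def test_alt_reads_boundary(self):
        assert "alt_reads" in hard_filter(_row(alt_fwd=5, alt_rev=4), CFG)
        assert hard_filter(_row(alt_fwd=6, alt_rev=4), CFG) == []

    def test_strand_imbalance(self):
        # 12 alt reads but 3/9 by strand fails the per-strand minimum
        assert hard_filter(_row(alt_fwd=3, alt_rev=9), CFG) == ["strand"]

    def test_population_maf_and_repeat(self):
        assert "population_maf" in hard_filter(_row(population_maf=0.02), CFG)
        assert "repeat" in hard_filter(_row(repeat_flag=1), CFG)

    def test_multiple_reasons_enumerated(self):
        reasons = hard_filter(_row(100, 100, 2, 1, 0.5, 1), CFG)
        assert set(reasons) == {"depth", "alt_reads", "strand",
                                "population_maf", "repeat"}

    def test_malformed_row(self):
        with pytest.raises(ValueError):
            hard_filter({"depth_fwd": 1}, CFG)


class TestFitSiteErrorModel:
    def test_all_zero_gives_floor(self):
        model = fit_site_error_model([0] * 170, [5000] * 170, CFG)
        assert model.error_rate == CFG.pseudo_error_floor
        assert model.overdispersion == 0.0

    def test_constant_ratio_no_dispersion(self):
        alts = [5] * 100
        model = fit_site_error_model(alts, [5000] * 100, CFG)
        assert model.overdispersion == pytest.approx(0.0, abs=1e-4)

    def test_parameter_recovery(self):
        """Method-of-moments recovery from beta-binomial data: e within
        +/-30%, rho within +/-50%, averaged over replicates."""
        e_true, rho_true, depth, n = 1e-3, 0.01, 5000, 170
        a = e_true * (1 - rho_true) / rho_true
        b = (1 - e_true) * (1 - rho_true) / rho_true
        rng = np.random.default_rng(0)
        es, rhos = [], []
        for _ in range(100):
            p = rng.beta(a, b, size=n)
            alts = rng.binomial(depth, p)
            m = fit_site_error_model(alts, [depth] * n, CFG)
            es.append(m.error_rate)
            rhos.append(m.overdispersion)
        assert np.mean(es) == pytest.approx(e_true, rel=0.3)
        assert np.mean(rhos) == pytest.approx(rho_true, rel=0.5)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_site_error_model([1], [100], CFG)


class TestSitePvalue:
    def test_zero_alt_is_one(self):
        model = SiteErrorModel(1e-3, 0.01, 100)
        assert site_pvalue(0, 5000, model) == 1.0

    def test_binomial_reduction(self):
        # summation oracle: with rho=0 the tail equals the binomial survival
        model = SiteErrorModel(1e-3, 0.0, 100)
        direct = sum(stats.binom.pmf(k, 5000, 1e-3) for k in range(25, 5001))
        assert site_pvalue(25, 5000, model) == pytest.approx(direct, rel=1e-9)

    def test_dispersion_monotonicity(self):
        # heavier dispersion -> heavier upper tail, throughout the regime
        # where the Beta mixing density is unimodal near the error rate
        # (at extreme rho the Beta collapses onto 0 and the tail shrinks
        # again, so global monotonicity in rho does not hold)
        ps = [site_pvalue(25, 5000, SiteErrorModel(1e-3, rho, 100))
              for rho in (0.0, 1e-5, 1e-4, 1e-3, 1e-2)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_alt_above_depth(self):
        with pytest.raises(ValueError):
            site_pvalue(10, 5, SiteErrorModel(1e-3, 0.0, 10))


class TestBHAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_never_more_discoveries_than_uncorrected(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200) ** 2
        alpha = 0.05
        assert (bh_adjust(p) <= alpha).sum() <= (p <= alpha).sum()

    def test_empty(self):
        assert len(bh_adjust([])) == 0


class TestClassifyVariants:
    def test_planted_classes_recovered(self, default_study):
        """End-to-end on the full synthetic cohort: planted SRMs are called
        SRM, haematopoietic MRMs are called MRM, germline is separated, and
        no unplanted site is called SRM or MRM."""
        _, reads, truth = default_study
        classified = classify_variants(reads)
        tkey = truth.groupby(["individual_id", "panel", "gene_label",
                              "position"])["truth_class"].first()
        calls = {}
        for v in classified:
            t = tkey.get((v.individual_id, v.panel, v.gene_label,
                          v.position), "none")
            calls.setdefault(t, []).append(v.label)
        srm_calls = calls.get("SRM-developmental", [])
        assert srm_calls and srm_calls.count("SRM") / len(srm_calls) >= 0.7
        mrm_calls = calls.get("MRM-haematopoietic", [])
        assert mrm_calls and mrm_calls.count("MRM") / len(mrm_calls) >= 0.7
        germ = calls.get("germline", [])
        assert germ and germ.count("germline") / len(germ) >= 0.9
        for label in calls.get("none", []):
            assert label == "rejected"

    def test_row_order_invariance(self, small_study):
        _, reads, _ = small_study
        a = classify_variants(reads)
        shuffled = reads.sample(frac=1.0, random_state=1)
        b = classify_variants(shuffled)
        key = lambda v: (v.site, v.individual_id)
        assert {key(v): v.label for v in a} == {key(v): v.label for v in b}

    def test_null_study_has_no_discoveries(self):
        """Error-only cohorts: the study-wide probability of any SRM call
        stays at or below the BH alpha (checked across replicates)."""
        cfg = dict(n_control=3, n_ad=3, n_lb=3,
                   region_design={"CB": 9, "EC": 9, "FC": 9},
                   n_blood_paired=0, rate=0.0, mrm_per_brain=0.0,
                   n_germline_per_individual=0, n_background_sites=30)
        rng = np.random.default_rng(31)
        studies_with_srm = 0
        n_rep = 25
        for _ in range(n_rep):
            reads, _ = generate_study(StudyConfig(**cfg), rng)
            classified = classify_variants(reads)
            studies_with_srm += any(v.label in ("SRM", "MRM")
                                    for v in classified)
        # binomial error allowance around alpha = 0.05
        assert studies_with_srm <= stats.binom.ppf(0.995, n_rep, 0.05)


class TestSpikeInPerformance:
    def test_operating_point(self):
        """Spike-in mixtures at ~5000x: >= 0.9 sensitivity at the 0.5% VAF
        level and >= 0.99 specificity on error-only sites."""
        reads, truth = spike_in_mixture(n_het_sites=100, n_null_sites=300,
                                        rng=8)
        detected = detect_spike_ins(reads)
        perf = screen_performance(detected, truth).set_index("true_vaf")
        assert perf.loc[0.005, "sensitivity"] >= 0.9
        assert perf.loc[0.0, "specificity"] >= 0.99
        # higher levels detect at least as well
        assert perf.loc[0.02, "sensitivity"] >= perf.loc[0.005, "sensitivity"]

    def test_perfect_and_all_reject_classifiers(self):
        truth = pd.DataFrame({
            "panel": ["case"] * 2, "gene_label": ["G1", "G1"],
            "position": [1, 2], "ref": ["A", "A"], "alt": ["T", "T"],
            "sample_id": ["s1", "s1"], "true_vaf": [0.01, 0.02],
            "individual_id": ["m", "m"], "truth_class": ["spike-in"] * 2,
            "generation": [None, None],
        })
        detected = truth[["panel", "gene_label", "position", "ref", "alt",
                          "sample_id"]].copy()
        detected["detected"] = True
        perf = screen_performance(detected, truth)
        sens = perf.set_index("true_vaf")["sensitivity"]
        assert (sens.dropna() == 1.0).all()
        detected["detected"] = False
        perf = screen_performance(detected, truth)
        sens = perf.set_index("true_vaf")["sensitivity"]
        assert (sens.dropna() == 0.0).all()

    def test_empty_bins_undefined(self):
        truth = pd.DataFrame(columns=["panel", "gene_label", "position",
                                      "ref", "alt", "sample_id", "true_vaf"])
        detected = pd.DataFrame(columns=["panel", "gene_label", "position",
                                         "ref", "alt", "sample_id",
                                         "detected"])
        perf = screen_performance(detected, truth, vaf_bins=[0.01])
        assert np.isnan(perf.iloc[0]["sensitivity"])
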