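"""Validation statistics: region means, age-adjusted regression (with
Firth fallback), longitudinal stability, mosaic dilution, and the
cell-mixture explainability test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trisomethyl.simulate import generate_pyroseq_group, panel_gene
from trisomethyl.types import ValidationError
from trisomethyl.validation import (
    MixtureSpec,
    age_adjusted_group_test,
    cohort_stability_summary,
    mixture_explained,
    mosaic_dilution_predict,
    mosaic_fraction_estimate,
    mosaic_fraction_estimate_panel,
    pyroseq_region_mean,
    pyroseq_sample_means,
    stability_over_time,
)


class TestRegionMean:
    def test_constant_region(self):
        assert pyroseq_region_mean([50.0] * 8) == 50.0

    def test_too_few_cpgs_not_reportable(self):
        with pytest.raises(ValidationError, match="at least 8"):
            pyroseq_region_mean([50.0] * 7)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, 10)
        assert pyroseq_region_mean(vals) == pytest.approx(float(np.mean(vals)))


class TestAgeAdjustedTest:
    def simulate_gene(self, gene, n_ds, n_ctrl, seed):
        spec = panel_gene(gene)
        ds = generate_pyroseq_group(spec, "DS", n_ds, seed=seed)
        ctrl = generate_pyroseq_group(spec, "control", n_ctrl, seed=seed + 1)
        both = pd.concat([ds, ctrl], ignore_index=True)
        means = pyroseq_sample_means(both)
        meta = both.drop_duplicates("sample_id").set_index("sample_id")[["age", "group"]]
        return means.join(meta, on="sample_id")

    def test_strong_panel_gene_highly_significant_at_printed_sizes(self):
        df = self.simulate_gene("TMEM131", 207, 73, seed=60)
        res = age_adjusted_group_test(df["region_mean"] / 100, df["age"], df["group"])
        assert res["p_methylation"] < 1e-4
        assert res["firth"]  # dichotomous groups separate: Firth fallback

    def test_overlapping_gene_uses_plain_wald(self):
        df = self.simulate_gene("SUMO3", 98, 39, seed=61)
        res = age_adjusted_group_test(df["region_mean"] / 100, df["age"], df["group"])
        assert res["p_methylation"] < 1e-4
        assert res["method"] == "ml_wald"

    def test_null_calibration_at_five_percent(self):
        rng = np.random.default_rng(7)
        n_reps, n = 400, 40
        rejections = 0
        for _ in range(n_reps):
            meth = rng.uniform(0.2, 0.8, n)
            age = rng.uniform(20, 70, n)
            group = np.array(["DS"] * (n // 2) + ["control"] * (n // 2))
            res = age_adjusted_group_test(meth, age, group)
            rejections += res["p_methylation"] < 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_reps) + 0.01

    def test_age_translation_leaves_p_unchanged(self):
        df = self.simulate_gene("SUMO3", 40, 40, seed=62)
        r1 = age_adjusted_group_test(df["region_mean"] / 100, df["age"], df["group"])
        r2 = age_adjusted_group_test(df["region_mean"] / 100, df["age"] + 17.0,
                                     df["group"])
        assert r1["p_methylation"] == pytest.approx(r2["p_methylation"], rel=1e-5)

    def test_constant_age_reduces_to_unadjusted_fit(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        meth = rng.uniform(0, 1, 40)
        group = np.where(meth + rng.normal(0, 0.4, 40) > 0.5, "DS", "control")
        if len(set(group)) < 2:
            pytest.skip("degenerate draw")
        res = age_adjusted_group_test(meth, np.full(40, 30.0), group)
        y = (group == "DS").astype(float)
        fit = sm.Logit(y, sm.add_constant(meth)).fit(disp=0)
        assert res["p_methylation"] == pytest.approx(float(fit.pvalues[1]), rel=1e-6)

    def test_constant_methylation_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            age_adjusted_group_test(np.full(20, 0.5), np.arange(20),
                                    np.array(["DS", "control"] * 10))


class TestStability:
    def make_values(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "gene",
                                           "timepoint_index", "region_mean"])

    def test_identical_timepoints_give_zero_range(self):
        df = self.make_values([("i1", "G", 0, 30.0), ("i1", "G", 1, 30.0)])
        out = stability_over_time(df)
        assert out.loc[0, "range"] == 0.0

    def test_range_arithmetic(self):
        df = self.make_values([("i1", "G", 0, 30.0), ("i1", "G", 1, 36.0)])
        assert stability_over_time(df).loc[0, "range"] == pytest.approx(6.0)

    def test_single_timepoint_excluded(self):
        df = self.make_values([("i1", "G", 0, 30.0), ("i2", "G", 0, 40.0),
                               ("i2", "G", 1, 41.0)])
        out = stability_over_time(df)
        assert list(out["individual_id"]) == ["i2"]

    def test_median_range_bounded_under_small_within_noise(self):
        # within-individual SD of 2 percentage points across draws
        rng = np.random.default_rng(9)
        rows = []
        for i in range(60):
            base = rng.uniform(20, 60)
            for tp in range(2):
                rows.append((f"i{i}", "G", tp, base + rng.normal(0, 2.0)))
        out = stability_over_time(self.make_values(rows))
        assert cohort_stability_summary(out)["median_range"] < 6.0


class TestMosaicDilution:
    def test_endpoints(self):
        assert mosaic_dilution_predict(0.10, 0.40, 1.0) == pytest.approx(0.10)
        assert mosaic_dilution_predict(0.10, 0.40, 0.0) == pytest.approx(0.40)

    def test_midpoint_arithmetic(self):
        assert mosaic_dilution_predict(0.10, 0.40, 0.5) == pytest.approx(0.25)

    @given(f=st.floats(min_value=0.0, max_value=1.0),
           mu_tri=st.floats(min_value=0.0, max_value=1.0),
           mu_di=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_predict_estimate_inverse_identity(self, f, mu_tri, mu_di):
        if abs(mu_tri - mu_di) < 1e-6:
            return
        obs = mosaic_dilution_predict(mu_tri, mu_di, f)
        assert mosaic_fraction_estimate(obs, mu_tri, mu_di) == pytest.approx(f, abs=1e-7)

    def test_uninformative_locus_rejected(self):
        with pytest.raises(ValidationError, match="uninformative"):
            mosaic_fraction_estimate(0.3, 0.4, 0.4)

    def test_panel_estimate_recovers_fraction(self):
        # nine-gene panel, true mosaic fraction 0.3, beta noise per gene
        from trisomethyl.simulate import TABLE1_PANEL, SHAPE_DISPERSION
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(3000 + s)
            observed, mu_tri, mu_di, var = {}, {}, {}, {}
            for spec in TABLE1_PANEL:
                mu = 0.3 * spec.mu_ds + 0.7 * spec.mu_ctrl
                disp = spec.effective_dispersion
                a, b = mu * disp, (1 - mu) * disp
                observed[spec.gene] = rng.beta(a, b)
                mu_tri[spec.gene] = spec.mu_ds
                mu_di[spec.gene] = spec.mu_ctrl
                var[spec.gene] = mu * (1 - mu) / (disp + 1)
            res = mosaic_fraction_estimate_panel(observed, mu_tri, mu_di, var)
            hits += abs(res["f_hat"] - 0.3) <= 0.15
        # the panel's inter-individual dispersion bounds single-sample
        # precision: the weighted estimator's SD is ~0.075, so +-0.15
        # (2 SD) captures ~95% of draws
        assert hits >= 0.95 * n_seeds

    def test_panel_with_no_informative_locus_rejected(self):
        with pytest.raises(ValidationError):
            mosaic_fraction_estimate_panel({"G": 0.5}, {"G": 0.4}, {"G": 0.4})


class TestMixtureExplained:
    def test_equal_methylation_across_types_explains_nothing(self):
        spec = MixtureSpec(("a", "b"), (0.4, 0.4), (0.0, 0.0), (1.0, 1.0), (0.5, 0.5))
        res = mixture_explained(0.05, spec)
        assert res["max_achievable_shift"] == pytest.approx(0.0)
        assert not res["explainable"]

    def test_two_type_free_box_matches_grid_oracle(self):
        spec = MixtureSpec(("a", "b"), (0.2, 0.8), (0.0, 0.0), (1.0, 1.0), (0.6, 0.4))
        res = mixture_explained(0.3, spec)
        # brute-force grid over the single free proportion
        w1 = np.linspace(0, 1, 1_000_001)
        bulk = w1 * 0.2 + (1 - w1) * 0.8
        ref = 0.6 * 0.2 + 0.4 * 0.8
        oracle = float(np.max(np.abs(bulk - ref)))
        assert res["max_achievable_shift"] == pytest.approx(oracle, abs=1e-6)

    def test_bounded_box_matches_grid_oracle(self):
        m = np.array([0.1, 0.5, 0.9])
        lo = np.array([0.2, 0.1, 0.05])
        hi = np.array([0.7, 0.6, 0.3])
        w0 = np.array([0.55, 0.35, 0.10])
        spec = MixtureSpec(("a", "b", "c"), tuple(m), tuple(lo), tuple(hi), tuple(w0))
        res = mixture_explained(0.1, spec)
        # grid over two free coordinates; third = 1 - sum
        grid = np.linspace(0, 1, 701)
        wa, wb = np.meshgrid(grid, grid, indexing="ij")
        wc = 1.0 - wa - wb
        ok = ((wa >= lo[0]) & (wa <= hi[0]) & (wb >= lo[1]) & (wb <= hi[1])
              & (wc >= lo[2] - 1e-12) & (wc <= hi[2] + 1e-12))
        bulk = wa * m[0] + wb * m[1] + wc * m[2]
        ref = float(w0 @ m)
        oracle = float(np.max(np.abs(bulk[ok] - ref)))
        assert res["max_achievable_shift"] == pytest.approx(oracle, abs=2e-3)
        assert res["max_achievable_shift"] >= oracle - 1e-9

    def test_symmetric_in_sign_of_observed_difference(self):
        spec = MixtureSpec(("a", "b"), (0.2, 0.8), (0.1, 0.1), (0.9, 0.9), (0.5, 0.5))
        r_pos = mixture_explained(0.2, spec)
        r_neg = mixture_explained(-0.2, spec)
        assert r_pos["explainable"] == r_neg["explainable"]
        assert r_pos["max_achievable_shift"] == r_neg["max_achievable_shift"]

    def test_directionally_plausible_vs_implausible_specs(self):
        # CD3Z-like: mononuclear cells much less methylated than PMN, and
        # lymphocyte excursions within plausible counts can reproduce the
        # observed 13-point drop in DS bulk methylation
        cd3z = MixtureSpec(
            ("pmn", "lymphocyte"), (0.35, 0.00),
            (0.25, 0.15), (0.85, 0.75), (0.65, 0.35))
        assert mixture_explained(-0.13, cd3z)["explainable"]
        # TMEM131-like: NK cells slightly HYPERmethylated, so even a large
        # NK excess moves bulk the wrong way / far too little to explain
        # the 30-point hypomethylation in DS
        tmem = MixtureSpec(
            ("other", "nk"), (0.41, 0.45),
            (0.85, 0.02), (0.98, 0.15), (0.96, 0.04))
        assert not mixture_explained(-0.302, tmem)["explainable"]

    def test_infeasible_box_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            MixtureSpec(("a", "b"), (0.2, 0.8), (0.6, 0.6), (0.7, 0.7), (0.5, 0.5))
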