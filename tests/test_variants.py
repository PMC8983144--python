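"""Relative metrics, group statistics, classification, and pharmacology."""

import numpy as np
import pandas as pd
import pytest

from mcurrent.variants import (ClassificationError, PlatePairingError,
                               VariantResult, classify_heterozygous,
                               classify_homozygous, classify_variant,
                               compare_groups, relative_metrics,
                               retigabine_response)


def cell_table(densities, v_halfs=None, plate="plate0", voltage_col="density_40"):
    n = len(densities)
    if v_halfs is None:
        v_halfs = [-18.9] * n
    return pd.DataFrame({voltage_col: densities, "v_half": v_halfs,
                         "plate": [plate] * n})


class TestRelativeMetrics:
    def test_identical_cohorts_are_100_percent(self):
        df = cell_table([10.0, 20.0, 30.0])
        m = relative_metrics(df, df.copy(), include_tau=False)
        assert m.percent_wt_density == pytest.approx(100.0)
        assert m.delta_vhalf == pytest.approx(0.0)

    def test_scaled_density_and_shifted_vhalf(self):
        wt = cell_table([10.0, 20.0, 30.0])
        var = cell_table([4.0, 8.0, 12.0], v_halfs=[-8.9, -8.9, -8.9])
        m = relative_metrics(var, wt, include_tau=False)
        assert m.percent_wt_density == pytest.approx(40.0)
        assert m.delta_vhalf == pytest.approx(10.0)

    def test_tau_ratio_per_voltage(self):
        wt = cell_table([10.0, 10.0]).assign(tau_m20=[100.0, 100.0])
        var = cell_table([10.0, 10.0]).assign(tau_m20=[200.0, 200.0])
        m = relative_metrics(var, wt)
        assert m.tau_ratio == {-20.0: pytest.approx(2.0)}

    def test_cross_plate_comparison_refused(self):
        wt = cell_table([10.0, 20.0], plate="A")
        var = cell_table([10.0, 20.0], plate="B")
        with pytest.raises(PlatePairingError):
            relative_metrics(var, wt)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            relative_metrics(cell_table([]), cell_table([10.0]))


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        assert compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_textbook_t_test(self):
        # [1,2,3] vs [4,5,6]: t = -3.674 on 4 df -> p ~ 0.0213
        p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], mode="ttest")
        assert p == pytest.approx(0.02131164, abs=1e-6)

    def test_anova_matches_reference_implementation(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        groups = [[1.1, 2.0, 2.9, 3.2], [4.0, 4.8, 5.1, 6.2], [2.5, 3.3, 3.1, 2.2]]
        p = compare_groups(*groups, mode="anova")
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [len(g) for g in groups])})
        table = sm.stats.anova_lm(ols("y ~ C(g)", data=df).fit(), typ=1)
        assert p == pytest.approx(float(table["PR(>F)"].iloc[0]), abs=1e-10)

    def test_separated_cohorts_significant(self):
        rng = np.random.default_rng(21)
        lo = 10.0 * (1 + 0.5 * rng.standard_normal(30))
        hi = 100.0 * (1 + 0.5 * rng.standard_normal(30))
        assert compare_groups(lo, hi) < 0.01

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestClassification:
    SIG, NS = 0.001, 0.6

    @pytest.mark.parametrize("pct,expected", [
        (8.0, "profound_LOF"),
        (10.0, "profound_LOF"),   # inclusive boundary
        (10.1, "severe_LOF"),
        (24.9, "severe_LOF"),
        (25.0, "partial_LOF"),    # half-open bin edge
        (74.9, "partial_LOF"),
        (75.0, "WT_like"),        # outside the partial band
    ])
    def test_homozygous_density_bins(self, pct, expected):
        assert classify_homozygous(pct, 0.0, self.SIG, self.NS) == expected

    def test_density_bins_require_significance(self):
        assert classify_homozygous(8.0, 0.0, self.NS, self.NS) == "WT_like"

    @pytest.mark.parametrize("dv,expected", [
        (-8.0, "GOF_shift"), (8.0, "LOF_shift"),
        (-5.0, "GOF_shift"), (5.0, "LOF_shift"),   # inclusive 5 mV boundary
        (-4.9, "WT_like"), (4.9, "WT_like"),
    ])
    def test_vhalf_shift_classes(self, dv, expected):
        assert classify_homozygous(98.0, dv, self.NS, self.SIG) == expected

    def test_shift_requires_significance(self):
        assert classify_homozygous(98.0, -8.0, self.NS, self.NS) == "WT_like"

    @pytest.mark.parametrize("pct,p,expected", [
        (40.0, SIG, "DN"),
        (49.9, SIG, "DN"),
        (50.0, SIG, "pR"),        # boundary: DN is strictly below 50%
        (70.0, SIG, "pR"),
        (100.0, NS, "fR"),
        (60.0, NS, "fR"),         # not significant -> full rescue
        (130.0, SIG, "enhanced"),
    ])
    def test_heterozygous_rescue_classes(self, pct, p, expected):
        assert classify_heterozygous(pct, p) == expected

    def test_classify_variant_requires_p_values_and_n(self):
        r = VariantResult(variant="V1", zygosity="homozygous",
                          percent_wt_density=8.0, delta_vhalf=0.0,
                          n_variant=5, n_wt=5)
        with pytest.raises(ClassificationError):
            classify_variant(r)
        r.p_density = 0.001
        r.n_variant = 1
        with pytest.raises(ClassificationError):
            classify_variant(r)
        r.n_variant = 5
        assert classify_variant(r).class_homozygous == "profound_LOF"

    def test_every_metric_triple_maps_to_exactly_one_label(self):
        percents = [0.0, 5.0, 10.0, 17.0, 25.0, 40.0, 74.9, 75.0, 90.0,
                    100.0, 120.0]
        dvs = [-12.0, -5.0, 0.0, 5.0, 12.0]
        ps = [self.SIG, self.NS, None]
        for pct in percents:
            for dv in dvs:
                for p_d in [self.SIG, self.NS]:
                    for p_v in ps:
                        hom = classify_homozygous(pct, dv, p_d, p_v)
                        het = classify_heterozygous(pct, p_d)
                        assert hom in ("profound_LOF", "severe_LOF",
                                       "partial_LOF", "WT_like",
                                       "GOF_shift", "LOF_shift")
                        assert het in ("DN", "pR", "fR", "enhanced")


class TestRetigabineResponse:
    def test_closed_form_wt_response_at_minus20(self, proto_1ms, fixed_covariates):
        from mcurrent.pipeline import analyze_cohort
        from mcurrent.simulate import DrugModel, SimConfig

        cfg = SimConfig(protocol=proto_1ms, covariates=fixed_covariates,
                        noise_rms=0.0, n_cells=2, seed=1)
        wt = analyze_cohort(cfg, None, "homozygous", group="WT")
        rtg = analyze_cohort(cfg, None, "homozygous",
                             drugs=((DrugModel(kind="retigabine"), 10.0),),
                             group="WT")
        resp = retigabine_response(rtg, wt, variant_control=wt, voltage=-20.0)
        # p_inf ratio at -20 mV (0.9425 / 0.4639) times the 1.4-fold
        # conductance increase ~ 284.5%
        assert resp.retigabine_pct == pytest.approx(284.5, abs=1.5)
        assert resp.control_pct == pytest.approx(100.0, abs=1e-9)
        assert resp.table is not None and len(resp.table) > 0

    def test_silent_channel_ignores_drug(self, proto_1ms, fixed_covariates):
        from mcurrent.pipeline import analyze_cohort
        from mcurrent.simulate import DrugModel, SimConfig, VariantEffect

        cfg = SimConfig(protocol=proto_1ms, covariates=fixed_covariates,
                        noise_rms=0.0, n_cells=2, seed=1)
        effect = VariantEffect(g_scale=0.0, dominance=1.0)
        wt = analyze_cohort(cfg, None, "homozygous", group="WT")
        hom = analyze_cohort(cfg, effect, "homozygous", group="V")
        hom_rtg = analyze_cohort(cfg, effect, "homozygous", group="V",
                                 drugs=((DrugModel(kind="retigabine"), 10.0),))
        resp = retigabine_response(hom_rtg, wt, variant_control=hom, voltage=-20.0)
        # no conductance -> the drug has nothing to act on
        assert resp.retigabine_pct == pytest.approx(resp.control_pct, abs=1e-6)
        assert resp.retigabine_pct == pytest.approx(0.0, abs=1e-6)

    def test_zero_wt_reference_rejected(self):
        wt = pd.DataFrame({"density_m20": [0.0, 0.0]})
        var = pd.DataFrame({"density_m20": [1.0, 1.0]})
        with pytest.raises(ValueError):
            retigabine_response(var, wt, voltage=-20.0)
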