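"""Generative model: gating kinetics, drug transforms, heterozygous mixing,
and cohort simulation contracts."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcurrent.processing import extract_features, subtract_background
from mcurrent.records import pair_by_cell
from mcurrent.simulate import (DrugModel, GatingParams, SimConfig, TauParams,
                               VariantEffect, apply_drug, apply_variant,
                               background_gating, boltzmann, effective_gating,
                               mix_heterozygous, nernst_potential,
                               open_probability, simulate_cohort, tau_of_v,
                               wt_gating)

WT = wt_gating()


class TestOpenProbability:
    def test_midpoint_is_half(self):
        assert open_probability(WT.v_half, 1e9, WT) == pytest.approx(0.5, abs=1e-9)

    def test_steady_state_at_plus40(self):
        # 1 / (1 + exp((-18.9 - 40) / 7.6))
        assert open_probability(40.0, 1e9, WT) == pytest.approx(0.9996, abs=5e-5)

    def test_initial_state_at_holding(self):
        # steady state at -80 mV: 1 / (1 + exp((-18.9 + 80) / 7.6))
        p0 = open_probability(-80.0, 0.0, WT, v_start=-80.0)
        assert p0 == pytest.approx(3.224e-4, rel=1e-3)

    def test_steady_state_matches_boltzmann_closed_form(self):
        v = np.linspace(-100, 60, 33)
        p = np.array([open_probability(float(x), 1e9, WT) for x in v])
        expected = 1.0 / (1.0 + np.exp((WT.v_half - v) / WT.slope))
        np.testing.assert_allclose(p, expected, atol=1e-12)

    @given(v=st.floats(-120, 60), t1=st.floats(0, 500), dt=st.floats(0.1, 500))
    def test_monotone_in_time_toward_steady_state(self, v, t1, dt):
        p_a = open_probability(v, t1, WT)
        p_b = open_probability(v, t1 + dt, WT)
        p_inf = float(boltzmann(v, WT))
        assert 0.0 <= p_a <= 1.0
        assert abs(p_inf - p_b) <= abs(p_inf - p_a) + 1e-12

    @given(v=st.floats(-120, 60), dv=st.floats(0.01, 50))
    def test_steady_state_monotone_in_voltage(self, v, dv):
        assert boltzmann(v + dv, WT) >= boltzmann(v, WT)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            open_probability(0.0, -1.0, WT)


class TestDrugs:
    def test_tea_at_ic50_halves_conductance(self):
        tea = DrugModel(kind="tea")
        out = apply_drug(WT, tea, tea.ic50)
        assert out.g_max == pytest.approx(WT.g_max / 2)

    def test_retigabine_shifts_vhalf_to_calibration(self):
        out = apply_drug(WT, DrugModel(kind="retigabine"), 10.0)
        assert out.v_half == pytest.approx(-47.7)
        assert out.slope == pytest.approx(9.9)
        assert out.g_max == pytest.approx(WT.g_max * 1.4)
        assert out.tau.tau_min == pytest.approx(WT.tau.tau_min * 0.5)

    def test_full_xe991_block_zeroes_m_conductance(self):
        out = apply_drug(WT, DrugModel(kind="xe991", block_fraction=1.0), 25.0)
        assert out.g_max == 0.0

    def test_zero_concentration_is_identity(self):
        assert apply_drug(WT, DrugModel(kind="tea"), 0.0) == WT

    def test_unknown_kind_rejected_at_construction(self):
        with pytest.raises(ValueError):
            DrugModel(kind="lidocaine")


class TestHeterozygousMixing:
    def test_identity_effect_returns_wt(self):
        eff = VariantEffect()
        out = mix_heterozygous(WT, apply_variant(WT, eff), eff)
        assert out.g_max == pytest.approx(WT.g_max)
        assert out.v_half == pytest.approx(WT.v_half)
        assert out.slope == pytest.approx(WT.slope)

    def test_dominant_negative_null_gives_quarter_conductance(self):
        eff = VariantEffect(g_scale=0.0, dominance=1.0)
        out = mix_heterozygous(WT, apply_variant(WT, eff), eff)
        assert out.g_max == pytest.approx(0.25 * WT.g_max)

    def test_haploinsufficient_null_gives_half_conductance(self):
        eff = VariantEffect(g_scale=0.0, dominance=0.0)
        out = mix_heterozygous(WT, apply_variant(WT, eff), eff)
        assert out.g_max == pytest.approx(0.50 * WT.g_max)

    @given(s=st.floats(0.0, 2.0))
    def test_additive_limit_is_allelic_mean(self, s):
        # with dominance 0 the effective conductance is (1 + s) / 2 of WT
        eff = VariantEffect(g_scale=s, dominance=0.0)
        out = mix_heterozygous(WT, apply_variant(WT, eff), eff)
        assert out.g_max == pytest.approx(WT.g_max * (1 + s) / 2, rel=1e-12)

    def test_pure_shift_variant_mixes_vhalf_halfway(self):
        eff = VariantEffect(delta_vhalf=10.0)
        out = mix_heterozygous(WT, apply_variant(WT, eff), eff)
        assert out.v_half == pytest.approx(WT.v_half + 5.0)


class TestCohortSimulation:
    def test_determinism_byte_level(self, proto_1ms):
        cfg = SimConfig(protocol=proto_1ms, n_cells=3, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert len(a) == len(b) == 6  # pre + post per cell
        for ra, rb in zip(a, b):
            assert ra.cell_id == rb.cell_id and ra.condition == rb.condition
            for v in proto_1ms.step_voltages:
                assert np.array_equal(ra.sweeps[v], rb.sweeps[v])

    def test_growing_cohort_preserves_earlier_cells(self, proto_1ms):
        small = simulate_cohort(SimConfig(protocol=proto_1ms, n_cells=2, seed=9))
        large = simulate_cohort(SimConfig(protocol=proto_1ms, n_cells=4, seed=9))
        for ra, rb in zip(small, large[:4]):
            assert np.array_equal(ra.sweeps[40.0], rb.sweeps[40.0])

    def test_nontransfected_has_no_xe991_sensitive_current(self, proto_1ms):
        cfg = SimConfig(protocol=proto_1ms, n_cells=6, seed=3)
        recs = simulate_cohort(cfg, zygosity="nontransfected")
        pairs = pair_by_cell(recs)
        dens = [extract_features(subtract_background(pre, post)).density_at(40.0)
                for pre, post in pairs]
        # XE991-sensitive density ~ 0: only subtraction noise remains
        assert abs(np.mean(dens)) < 1.0

    def test_noiseless_density_matches_closed_form(self, noiseless_config):
        recs = simulate_cohort(noiseless_config)
        pre, post = pair_by_cell(recs)[0]
        feats = extract_features(subtract_background(pre, post), window_ms=0.0)
        g = effective_gating(noiseless_config, None, "homozygous")
        p999 = open_probability(40.0, 999.0, g)
        expected = g.g_max * p999 * (40.0 - g.e_rev) / 8.0
        assert feats.density_at(40.0) == pytest.approx(expected, rel=1e-9)

    def test_invalid_zygosity_rejected(self, proto_1ms):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(protocol=proto_1ms, n_cells=1, seed=0),
                            zygosity="triploid")


def test_nernst_potential_for_recording_solutions():
    # 4 mM out / 110 mM in at 295 K
    assert nernst_potential() == pytest.approx(-84.2, abs=0.1)


def test_background_calibrated_to_twentyfold_contrast():
    bg = background_gating()
    assert bg.g_max > 0
    # nontransfected density must be far below the WT M-current density
    wt = wt_gating()
    m = wt.g_max * float(boltzmann(40.0, wt)) * (40.0 - wt.e_rev)
    b = bg.g_max * float(boltzmann(40.0, bg)) * (40.0 - bg.e_rev)
    assert m / b > 10


def test_tau_is_positive_and_decreasing_with_depolarization():
    tau = TauParams()
    v = np.linspace(-80, 40, 25)
    taus = tau_of_v(v, tau)
    assert np.all(taus > 0)
    assert np.all(np.diff(taus) <= 0)


def test_invariants_rejected():
    with pytest.raises(ValueError):
        GatingParams(g_max=1.0, v_half=0.0, slope=-1.0)
    with pytest.raises(ValueError):
        VariantEffect(dominance=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_cells=0)
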