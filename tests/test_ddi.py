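"""DDI engine: Guest envelope, perpetrator PK, inhibition co-simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rosupbpk as rp
from rosupbpk.calibration import set_param
from rosupbpk.ddi import ConfigurationError, InhibitionSpec, PerpetratorModel
from rosupbpk.dosing import SPLIT_LAG_H


class TestGuestLimits:
    def test_unity_ratio_gives_bioequivalence_band(self):
        lo, hi = rp.guest_limits(1.0)
        assert lo == pytest.approx(0.8)
        assert hi == pytest.approx(1.25)

    def test_ratio_two(self):
        lo, hi = rp.guest_limits(2.0)
        assert lo == pytest.approx(2.0 / 1.625)
        assert hi == pytest.approx(3.25)

    def test_strong_interaction_approaches_twofold(self):
        r = 1e6
        lo, hi = rp.guest_limits(r)
        assert lo == pytest.approx(r / 2.0, rel=1e-4)
        assert hi == pytest.approx(2.0 * r, rel=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rp.guest_limits(0.0)

    @settings(derandomize=True, max_examples=80)
    @given(pred=st.floats(0.05, 20.0), obs=st.floats(0.05, 20.0))
    def test_reciprocal_symmetry(self, pred, obs):
        assert rp.within_guest(pred, obs) == rp.within_guest(1.0 / pred, 1.0 / obs)

    @settings(derandomize=True, max_examples=50)
    @given(obs=st.floats(0.05, 50.0))
    def test_observed_ratio_inside_its_own_envelope(self, obs):
        lo, hi = rp.guest_limits(obs)
        assert lo < obs < hi


class TestPerpetratorConcentration:
    @pytest.fixture()
    def one_cpt(self):
        return PerpetratorModel("rifampicin", 822.94, cl_l_per_h=7.0, v1_l=55.0,
                                ka_per_h=1.15, f_bio=0.9, fu=0.2)

    def test_zero_before_first_dose(self, one_cpt):
        reg = rp.DosingProtocol("oral", 600.0, (rp.dosing.DoseEvent(4.0, 1.0),))
        assert rp.perpetrator_concentration(one_cpt, reg, [0.0, 3.9])[1] == 0.0

    def test_iv_bolus_textbook_solution(self, one_cpt):
        from rosupbpk.units import mg_to_umol

        reg = rp.iv_bolus(600.0)
        t = np.array([0.0, 2.0, 10.0])
        c = rp.perpetrator_concentration(one_cpt, reg, t)
        d = mg_to_umol(600.0, 822.94)
        expected = d / 55.0 * np.exp(-(7.0 / 55.0) * t)
        assert np.allclose(c, expected, rtol=1e-12)

    def test_superposition_two_half_doses_equal_one(self, one_cpt):
        t = np.linspace(0, 48, 97)
        single = rp.perpetrator_concentration(one_cpt, rp.oral_single(600.0), t)
        ev = (rp.dosing.DoseEvent(0.0, 0.5), rp.dosing.DoseEvent(0.0, 0.5))
        split = rp.perpetrator_concentration(
            one_cpt, rp.DosingProtocol("oral", 600.0, ev), t
        )
        assert np.allclose(single, split, rtol=1e-12)


class TestAbsorptionVariant:
    def test_rifampicin_and_probenecid_single_release(self):
        split = rp.oral_split(40.0)
        for perp in ("rifampicin", "probenecid"):
            out = rp.absorption_variant(split, perp)
            assert len(out.events) == 1
            assert out.events[0].start_time_h == 0.0
            assert out.events[0].dose_fraction == 1.0

    def test_gemfibrozil_and_none_keep_split(self):
        split = rp.oral_split(40.0)
        for perp in ("gemfibrozil", None):
            out = rp.absorption_variant(split, perp)
            assert len(out.events) == 2
            assert out.events[1].start_time_h == SPLIT_LAG_H

    def test_iv_protocol_rejected(self):
        with pytest.raises(ValueError):
            rp.absorption_variant(rp.iv_bolus(8.0), "rifampicin")


class TestSimulateDdi:
    def test_empty_specs_give_exact_unity(self, model, perpetrators):
        perps, _ = perpetrators
        res = rp.simulate_ddi(
            model, perps["rifampicin"], [], rp.oral_single(20.0),
            rp.oral_single(600.0), 36.0,
        )
        assert res.auc_last_ratio == 1.0
        assert res.cmax_ratio == 1.0

    def test_near_infinite_ki_is_identity(self, model, perpetrators):
        perps, _ = perpetrators
        specs = [InhibitionSpec("rifampicin", "OATP1B1_1B3", 1e12)]
        res = rp.simulate_ddi(
            model, perps["rifampicin"], specs, rp.oral_single(20.0),
            rp.oral_single(600.0), 36.0,
        )
        assert res.auc_last_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.cmax_ratio == pytest.approx(1.0, abs=1e-6)

    def test_rifampicin_raises_exposure_and_speeds_absorption(self, model, perpetrators):
        perps, spec_map = perpetrators
        grid = np.arange(0.0, 48.001, 0.1)
        res = rp.simulate_ddi(
            model, perps["rifampicin"], spec_map["rifampicin"],
            rp.absorption_variant(rp.oral_split(20.0), "rifampicin"),
            rp.oral_single(600.0), 48.0, output_grid_h=grid,
        )
        assert res.auc_last_ratio > 1.2
        assert res.cmax_ratio > 1.2
        # absorption switch: Cmax arrives well before the split-protocol peak
        control_split = rp.simulate(model, rp.oral_split(20.0), 48.0, grid)
        t_split = grid[np.argmax(control_split.plasma_concentration_umol_per_l)]
        t_ddi = grid[np.argmax(res.treated.plasma_concentration_umol_per_l)]
        assert t_ddi <= t_split - 1.0

    def test_unknown_target_rejected(self, model, perpetrators):
        perps, _ = perpetrators
        bad = [InhibitionSpec("rifampicin", "OAT3", 1.0)]
        from dataclasses import replace

        victim = replace(model, processes=tuple(p for p in model.processes if p.name != "OAT3"))
        with pytest.raises(ConfigurationError):
            rp.simulate_ddi(victim, perps["rifampicin"], bad, rp.oral_single(20.0),
                            rp.oral_single(600.0), 24.0)

    def test_static_equals_dynamic_for_constant_inhibitor(self, model):
        """A constant Km multiplier applied through the inhibition context
        matches a model whose Km is rescaled directly, point-wise."""
        grid = np.linspace(0.0, 48.0, 97)
        factor = 3.0
        ctx = {"OATP1B1_1B3": (lambda t: factor)}
        dynamic = rp.simulate(model.with_inhibition(ctx), rp.oral_split(20.0), 48.0, grid)
        km0 = model.process("OATP1B1_1B3").km_umol_per_l
        static_model = set_param(model, "process:OATP1B1_1B3@liver_basolateral:km", km0 * factor)
        static = rp.simulate(static_model, rp.oral_split(20.0), 48.0, grid)
        assert np.allclose(
            dynamic.plasma_concentration_umol_per_l,
            static.plasma_concentration_umol_per_l,
            rtol=1e-8, atol=1e-12,
        )

    def test_auc_ratio_monotone_in_perpetrator_dose(self, model, perpetrators):
        perps, _ = perpetrators
        specs = [InhibitionSpec("rifampicin", "OATP1B1_1B3", 0.63)]
        ratios = []
        for dose in (150.0, 600.0, 2400.0):
            res = rp.simulate_ddi(
                model, perps["rifampicin"], specs, rp.oral_single(20.0),
                rp.oral_single(dose), 36.0,
            )
            ratios.append(res.auc_last_ratio)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_gemfibrozil_metabolite_contributes(self, model, perpetrators):
        perps, spec_map = perpetrators
        gem = perps["gemfibrozil"]
        parent_only = [s for s in spec_map["gemfibrozil"] if s.perpetrator == "gemfibrozil"]
        reg = rp.oral_single(600.0, repeat_interval_h=12.0, n_repeats=3)
        with_met = rp.simulate_ddi(model, gem, spec_map["gemfibrozil"],
                                   rp.oral_split(80.0), reg, 48.0)
        without_met = rp.simulate_ddi(model, gem, parent_only,
                                      rp.oral_split(80.0), reg, 48.0)
        assert with_met.auc_last_ratio > without_met.auc_last_ratio > 1.0
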