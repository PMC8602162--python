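"""Core PBPK machinery: kinetics, physiology scaling, ODE properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rosupbpk as rp
from rosupbpk.model import _indices, pbpk_rhs
from rosupbpk.physiology import REFERENCE_PHYSIOLOGY
from rosupbpk.poppk import _conc_2cpt_iv_bolus_unit


# --------------------------------------------------------------------------
# Elementary kinetics
# --------------------------------------------------------------------------

class TestApparentKm:
    @pytest.mark.parametrize(
        "km,inh,ki,expected",
        [
            (3.7, 0.0, 1.0, 3.7),          # no inhibitor present
            (3.7, 2.0, 2.0, 7.4),          # I/Ki = 1 doubles Km
            (5.0, 0.63, 0.63, 10.0),       # rifampicin at its OATP1B1/1B3 Ki
        ],
    )
    def test_competitive_form(self, km, inh, ki, expected):
        assert rp.apparent_km(km, inh, ki) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        km=st.floats(1e-3, 1e4),
        i1=st.floats(0, 1e3),
        i2=st.floats(0, 1e3),
        ki=st.floats(1e-3, 1e3),
    )
    def test_monotone_in_inhibitor(self, km, i1, i2, ki):
        lo, hi = sorted([i1, i2])
        assert rp.apparent_km(km, lo, ki) <= rp.apparent_km(km, hi, ki)

    @pytest.mark.parametrize("km,inh,ki", [(1.0, 1.0, 0.0), (1.0, 1.0, -2.0), (0.0, 1.0, 1.0), (1.0, -1.0, 1.0)])
    def test_invalid_inputs(self, km, inh, ki):
        with pytest.raises(ValueError):
            rp.apparent_km(km, inh, ki)


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "conc,km,vmax,expected",
        [
            (0.0, 5.0, 100.0, 0.0),
            (5.0, 5.0, 100.0, 50.0),       # half-saturation
            (99 * 5.0, 5.0, 100.0, 99.0),  # near saturation
        ],
    )
    def test_saturable_rate(self, conc, km, vmax, expected):
        assert rp.michaelis_menten_rate(conc, km, vmax) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(conc=st.floats(0, 1e6), km=st.floats(1e-6, 1e6), vmax=st.floats(0, 1e6))
    def test_bounded_by_vmax(self, conc, km, vmax):
        assert 0.0 <= rp.michaelis_menten_rate(conc, km, vmax) <= vmax

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rp.michaelis_menten_rate(-1.0, 1.0, 1.0)


# --------------------------------------------------------------------------
# Physiology
# --------------------------------------------------------------------------

class TestBuildPhysiology:
    def test_reference_individual_is_unchanged(self):
        phys = rp.build_physiology(rp.REFERENCE_DEMOGRAPHICS)
        assert phys == REFERENCE_PHYSIOLOGY

    def test_double_weight_scales_volumes_and_flows(self):
        phys = rp.build_physiology(rp.Demographics(weight_kg=146.0))
        for organ, v in REFERENCE_PHYSIOLOGY.organ_volumes_l.items():
            assert phys.organ_volumes_l[organ] == pytest.approx(2 * v)
        for organ, q in REFERENCE_PHYSIOLOGY.blood_flows_l_per_h.items():
            assert phys.blood_flows_l_per_h[organ] == pytest.approx(2 * q)
        assert phys.gfr_l_per_h == pytest.approx(2 * REFERENCE_PHYSIOLOGY.gfr_l_per_h)
        # rates are size-invariant
        assert phys.intestinal_transit_rates_per_h == REFERENCE_PHYSIOLOGY.intestinal_transit_rates_per_h

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            rp.Demographics(weight_kg=0.0)


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

class TestRhs:
    def test_no_drug_no_flux(self, model):
        n = _indices(model.physiology.n_lumen_segments)["n"]
        dy = pbpk_rhs(0.0, np.zeros(n), model)
        assert np.all(dy == 0.0)

    def test_filtration_only_when_everything_else_off(self, stripped_model):
        m = stripped_model
        ix = _indices(m.physiology.n_lumen_segments)
        y = np.zeros(ix["n"])
        y[ix["PLA"]] = 10.0  # µmol in central plasma
        dy = pbpk_rhs(0.0, y, m)
        c = 10.0 / m.physiology.organ_volumes_l["plasma_central"]
        expected = m.physiology.gfr_l_per_h * m.compound.fraction_unbound_plasma * c
        assert dy[ix["URN"]] == pytest.approx(expected, rel=1e-12)
        # plasma loses filtration plus convective exchange (peripheral and
        # portal, both empty so fluxes are one-way out of plasma)
        q_out = m.physiology.plasma_flow("peripheral") + m.physiology.portal_plasma_flow
        assert dy[ix["PLA"]] == pytest.approx(-(expected + q_out * c), rel=1e-12)

    def test_mass_conservation_of_derivatives(self, model):
        rng = np.random.default_rng(0)
        ix = _indices(model.physiology.n_lumen_segments)
        for _ in range(5):
            y = rng.uniform(0, 5.0, size=ix["n"])
            dy = pbpk_rhs(1.0, y, model)
            # everything except the bile accumulator must cancel
            total = dy.sum() - dy[ix["BILE"]]
            assert abs(total) < 1e-12 * max(1.0, np.abs(dy).max())


# --------------------------------------------------------------------------
# Simulation properties
# --------------------------------------------------------------------------

class TestSimulate:
    def test_zero_dose_stays_zero(self, model):
        res = rp.simulate(model, rp.oral_split(0.0), 24.0, np.linspace(0, 24, 49))
        for name, a in res.amounts_umol.items():
            assert np.all(a == 0.0), name

    def test_closed_system_conserves_iv_bolus(self, stripped_model):
        from dataclasses import replace

        m = replace(
            stripped_model,
            physiology=replace(stripped_model.physiology, gfr_l_per_h=1e-12),
        )
        res = rp.simulate(m, rp.iv_bolus(8.0), 48.0, np.linspace(0, 48, 97))
        total = res.amounts_umol["plasma_central"] + res.amounts_umol["peripheral"]
        assert np.allclose(total[1:], res.dose_umol, rtol=1e-7)

    def test_mass_balance_within_tolerance(self, oral_40_result):
        assert oral_40_result.mass_balance_error() < 1e-6

    def test_trajectories_non_negative(self, oral_40_result):
        for name, a in oral_40_result.amounts_umol.items():
            assert np.all(a >= 0.0), name

    def test_oral_tmax_near_five_hours(self, model):
        grid = np.arange(0.0, 24.0001, 0.1)
        res = rp.simulate(model, rp.oral_split(40.0), 24.01, grid)
        tmax = grid[np.argmax(res.plasma_concentration_umol_per_l)]
        assert 4.0 <= tmax <= 6.0

    def test_dose_proportionality_in_linear_regime(self, linear_model):
        grid = np.linspace(0.0, 240.0, 481)
        aucs = {}
        for dose in (10.0, 20.0, 80.0):
            res = rp.simulate(linear_model, rp.oral_split(dose), 240.0, grid)
            aucs[dose] = rp.auc_last(res.times_h, res.plasma_concentration_ng_per_ml)
        assert aucs[20.0] / aucs[10.0] == pytest.approx(2.0, rel=1e-3)
        assert aucs[80.0] / aucs[10.0] == pytest.approx(8.0, rel=0.01)

    def test_infinite_ki_context_is_identity(self, model):
        grid = np.linspace(0.0, 48.0, 97)
        plain = rp.simulate(model, rp.oral_split(20.0), 48.0, grid)
        ctx = {p.name: (lambda t: 1.0 + 1.0 / np.inf) for p in model.processes}
        inhibited = rp.simulate(model.with_inhibition(ctx), rp.oral_split(20.0), 48.0, grid)
        assert np.allclose(
            plain.plasma_concentration_umol_per_l,
            inhibited.plasma_concentration_umol_per_l,
            rtol=1e-9, atol=1e-12,
        )

    def test_duration_must_exceed_last_dose(self, model):
        with pytest.raises(rp.SimulationError):
            rp.simulate(model, rp.oral_split(40.0), 1.0)


class TestTwoCompartmentOracle:
    def test_matches_analytic_biexponential(self, stripped_model):
        """Filtration-only IV simulation vs the closed-form 2-compartment
        solution, to < 0.1% everywhere the solution is non-negligible."""
        m = stripped_model
        phys, comp = m.physiology, m.compound
        grid = np.linspace(0.0, 96.0, 193)
        res = rp.simulate(m, rp.iv_bolus(8.0), 96.0, grid)
        cl = phys.gfr_l_per_h * comp.fraction_unbound_plasma
        v1 = phys.organ_volumes_l["plasma_central"]
        q = phys.plasma_flow("peripheral")
        v2 = phys.organ_volumes_l["peripheral"] * comp.peripheral_partition_coefficient
        dose_mg_equiv = res.dose_umol  # work in µmol: unit solution scales linearly
        analytic = dose_mg_equiv * _conc_2cpt_iv_bolus_unit(grid, cl, v1, v2, q)
        numeric = res.plasma_concentration_umol_per_l
        mask = analytic > analytic.max() * 1e-6
        assert np.max(np.abs(numeric[mask] - analytic[mask]) / analytic[mask]) < 1e-3
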