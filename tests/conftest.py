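import numpy as np
import pytest

import rosupbpk as rp
from rosupbpk.calibration import set_param


@pytest.fixture(scope="session")
def model():
    """Shipped calibrated rosuvastatin model."""
    return rp.load_default_model()


@pytest.fixture(scope="session")
def perpetrators():
    return rp.load_default_perpetrators()


@pytest.fixture(scope="session")
def stripped_model(model):
    """Filtration-only variant: no transporters, no absorption, no backflux.

    With all transit organs shrunk to negligible volume the system reduces
    exactly to a two-compartment model (central + flow-limited peripheral)
    with clearance GFR·fu, which has a closed-form bi-exponential solution.
    """
    m = model
    for p in model.processes:
        m = set_param(m, f"process:{p.key}:vmax", 0.0)
    from dataclasses import replace

    compound = replace(
        m.compound,
        intestinal_permeability_l_per_h=(0.0, 0.0, 0.0),
        enterocyte_basolateral_clearance_l_per_h=0.0,
        liver_backflux_clearance_l_per_h=0.0,
        kidney_backflux_clearance_l_per_h=0.0,
    )
    vols = dict(m.physiology.organ_volumes_l)
    for organ in ("portal_vein", "liver", "kidney", "gallbladder_bile", "enterocyte"):
        vols[organ] = 1e-6
    physiology = replace(m.physiology, organ_volumes_l=vols)
    return replace(m, compound=compound, physiology=physiology)


@pytest.fixture(scope="session")
def linear_model(model):
    """Calibrated model with every Km pushed far above attained
    concentrations (Vmax scaled along, so first-order clearances are
    unchanged) — the strictly dose-linear regime."""
    m = model
    for p in model.processes:
        m = set_param(m, f"process:{p.key}:km", p.km_umol_per_l * 1e6)
        m = set_param(m, f"process:{p.key}:vmax", p.vmax_scaled_umol_per_h * 1e6)
    return m


@pytest.fixture(scope="session")
def oral_40_result(model):
    grid = np.linspace(0.0, 240.0, 961)
    return rp.simulate(model, rp.oral_split(40.0), 240.0, grid)
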