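"""Shared fixtures: small, fast synthetic networks with solved oxygen fields."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import hapsim as hs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_BOX = (300.0, 250.0, 100.0)


@pytest.fixture(scope="session")
def small_tumor():
    """Compact tumor-like fixture (30×25×10 voxels), deterministic seed."""
    return hs.generate_tumor_like(seed=1, box=SMALL_BOX, n_vessels=5)


@pytest.fixture(scope="session")
def small_tumor_o2(small_tumor):
    net, dom = small_tumor
    return hs.solve_oxygen(net, dom, hs.OxygenParameters.tumor())


@pytest.fixture(scope="session")
def small_normal():
    return hs.generate_normal_like(seed=2, box=SMALL_BOX)


@pytest.fixture(scope="session")
def small_normal_o2(small_normal):
    net, dom = small_normal
    return hs.solve_oxygen(net, dom, hs.OxygenParameters.normal())


@pytest.fixture(scope="session")
def krogh():
    """Single-vessel cylinder geometry used as the analytic solver oracle."""
    return hs.generate_krogh(vessel_radius=0.5, domain_side=100.0, length=100.0,
                             flow=50.0, inflow_pO2=100.0, n_xy=21,
                             cylindrical_mask=True)


@pytest.fixture(scope="session")
def base_prodrug_effector(small_tumor, small_tumor_o2):
    """Base-model prodrug + effector transport on the small tumor fixture."""
    net, dom = small_tumor
    pp = hs.ProdrugParameters()
    ep = hs.EffectorParameters()
    psol = hs.solve_prodrug(net, dom, small_tumor_o2, pp)
    esol = hs.solve_effector(net, dom, small_tumor_o2, psol, ep)
    return pp, ep, psol, esol
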