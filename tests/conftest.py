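"""Shared fixtures: reference ladder, analytic slabs, and the coupled duct runs.

The duct session fixture runs the full tandem/alternate pipeline once at the
default resolution and is shared by the coupling, fieldmap and acceptance
tests to keep the suite within a sensible runtime.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from cfesim.cpe_network import CPEInterfaceParams, synthesize_network
from cfesim.interface_circuit import PulseSpec, FaradaicParams, simulate_interface
from cfesim.geometry import build_slab_fixture, build_duct_geometry, ElectrodeConfig
from cfesim.fem_poisson import assemble
from cfesim.coupling import SimulationPlan, run_simulation
from cfesim.fieldmap import bin_field_areas


SLAB_CONFIG = ElectrodeConfig(("anode", "cathode") + ("floating",) * 6)


@pytest.fixture(scope="session")
def reference_ladder():
    """Reference interface parameters and the synthesized 61-branch ladder."""
    params = CPEInterfaceParams()
    return params, synthesize_network(params)


@pytest.fixture(scope="session")
def slab():
    return build_slab_fixture()


@pytest.fixture(scope="session")
def slab_membrane():
    return build_slab_fixture(membrane=True)


@pytest.fixture(scope="session")
def plateau_potentials(reference_ladder):
    """End-of-plateau electrode potentials for the reported tissue loads."""
    params, net = reference_ladder
    pulse = PulseSpec(amplitude=20.0, width=50e-3, rise_time=1e-3, fall_time=1e-3)
    out = {}
    for name, r_tissue in (("tandem", 522.0), ("alternate", 174.0)):
        resp = simulate_interface(net, params.R_s, FaradaicParams(), r_tissue,
                                  pulse, dt_max=1e-6, store_every=50)
        out[name] = resp.at(pulse.width)["v_out"]
    return out


@pytest.fixture(scope="session")
def duct_session():
    """Default-resolution duct solved for both electrode configurations."""
    mesh = build_duct_geometry()
    system = assemble(mesh)
    results, reports = {}, {}
    for cfg in ("tandem", "alternate"):
        results[cfg] = run_simulation(SimulationPlan(mesh=mesh, config=cfg),
                                      system=system)
        reports[cfg] = bin_field_areas(results[cfg], config_name=cfg)
    return SimpleNamespace(mesh=mesh, system=system,
                           results=results, reports=reports)
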