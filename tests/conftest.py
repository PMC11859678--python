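import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hipecpk.boundary import OrganBoundarySeries, generate_boundary
from hipecpk.params import transport_defaults
from hipecpk.scenarios import DESK_SCALE, ScenarioRunner, organ_sweep
from hipecpk.tumor import NoduleGeometry, solve_nodule

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tumor_params():
    return transport_defaults("tumor")


@pytest.fixture(scope="session")
def host_params():
    return transport_defaults("normal")


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced host block for fast unit-level solves."""
    return NoduleGeometry(mesh_spacing=1.0e-4, host_extent=3.0e-3)


@pytest.fixture(scope="session")
def intestine_boundary():
    return generate_boundary("Intestine", 1)


@pytest.fixture(scope="session")
def control_field(small_geometry, tumor_params, host_params, intestine_boundary):
    """Untreated 160 µM HIPEC solve at the intestine site."""
    return solve_nodule(
        small_geometry, tumor_params, host_params, intestine_boundary,
        dt=2.0, snapshot_every=90,
    )


@pytest.fixture(scope="session")
def runner():
    """Shared desk-scale scenario runner (results cached across tests)."""
    return ScenarioRunner(DESK_SCALE)


@pytest.fixture(scope="session")
def sweep_results(runner):
    """Control + both bevacizumab arms, 7 organs x 2 catheter setups."""
    return organ_sweep(runner)


def constant_boundary(c0_mol_m3: float, temperature: float = 40.1) -> OrganBoundarySeries:
    """Boundary series pinned at a constant surface concentration."""
    return OrganBoundarySeries(
        organ_name="Intestine",
        setup=1,
        times=np.array([0.0, 3600.0]),
        surface_concentration=np.array([c0_mol_m3, c0_mol_m3]),
        surface_temperature=temperature,
    )


@pytest.fixture(scope="session")
def sinkless_params(tumor_params, host_params):
    """Pure-diffusion variants (beta = P_c = 0) for closed-form oracles."""
    return (
        dataclasses.replace(tumor_params, beta=0.0, P_c=0.0),
        dataclasses.replace(host_params, beta=0.0, P_c=0.0),
    )
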