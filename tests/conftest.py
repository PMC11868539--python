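import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lipidfoam as lf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hex_net():
    """4x4 honeycomb of 15 µm compartments (reference geometry)."""
    return lf.build_hexagonal_lattice(4, 4, 15.0)


@pytest.fixture(scope="session")
def uniform_tensions(hex_net):
    return {e: 1e-12 for e in hex_net.edges}


@pytest.fixture(scope="session")
def rendered_bundle():
    """Short active scenario with rendered stack and swimmers (2 blocks)."""
    cfg = lf.ScenarioConfig(seed=7, duration_s=120, n_rows=3, n_cols=3)
    return lf.generate_scenario(cfg)


@pytest.fixture(scope="session")
def paired_bundles():
    """Matched active / heat-killed scenarios, tracks only (no rendering)."""
    ca = lf.ScenarioConfig(
        seed=3, duration_s=600, n_rows=5, n_cols=5, mode="active",
        render=False, simulate_swimmers=False,
    )
    cp = ca.model_copy(update={"mode": "heat-killed"})
    return lf.generate_scenario(ca), lf.generate_scenario(cp)


@pytest.fixture(scope="session")
def passive_trajectory(hex_net, uniform_tensions):
    cfg = lf.SimulationConfig(dt=0.5, duration=600.0, sampling_interval=1.0, f0=1e-4, seed=21)
    return lf.simulate_network_dynamics(hex_net, uniform_tensions, cfg, occupancy=None, seed=21)


def ou_tracks(n, teff_ratio, seed0, duration=600.0):
    """Ensemble of overdamped-junction tracks at the standard acquisition."""
    out = []
    for i in range(n):
        cfg = lf.SimulationConfig(
            dt=0.1, duration=duration, sampling_interval=1.0,
            teff_ratio=teff_ratio, seed=seed0 + i,
        )
        out.append(lf.simulate_ou_vertex(cfg, vertex_id=i))
    return out
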