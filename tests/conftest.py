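import numpy as np
import pytest

from gagcg.fixtures import make_known_bonded_potentials
from gagcg.simulator import SimulationConfig, minimize, run_simulation, system_from_topology
from gagcg.topology import build_gag_chain, initial_conformation


@pytest.fixture(scope="session")
def ha16():
    return build_gag_chain("HA", 16)


@pytest.fixture(scope="session")
def known_pots():
    return make_known_bonded_potentials(0)


@pytest.fixture(scope="session")
def ha16_system(ha16, known_pots):
    return system_from_topology(ha16, known_pots, nonbonded_on=True)


@pytest.fixture(scope="session")
def ha16_minimized(ha16, ha16_system):
    return minimize(ha16_system, initial_conformation(ha16, 1))


@pytest.fixture(scope="session")
def ha16_short_traj(ha16_system, ha16_minimized):
    """Short bonded+nonbonded run shared by analysis-level tests."""
    cfg = SimulationConfig(dt_fs=5.0, friction=5.0, n_steps=100_000,
                           record_every=100, seed=11)
    return run_simulation(ha16_system, cfg, positions=ha16_minimized)
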