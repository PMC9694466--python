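import numpy as np
import pytest

from switchscope.system import ParamStructure
from switchscope.toytraj import (
    GeneratorConfig,
    generate_topology,
    generate_trajectory,
    state_references,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def toy_structure(default_config):
    return generate_topology(default_config)


@pytest.fixture(scope="session")
def state_refs(default_config, toy_structure):
    return state_references(default_config, toy_structure)


@pytest.fixture(scope="session")
def toy_run(default_config, toy_structure, state_refs):
    """A 2000-frame default trajectory with its truth manifest (seed 11)."""
    traj, manifest = generate_trajectory(
        toy_structure,
        np.array(default_config.hidden_T),
        state_refs,
        default_config.noise_sd,
        2000,
        seed=11,
    )
    return traj, manifest


def make_structure(n, charges=None, rmin2=None, epsilon=None, born=None,
                   bonds=(), roles=None, elements=None, **flags):
    """Small ad-hoc structure for unit tests."""
    return ParamStructure(
        names=np.array([f"X{i}" for i in range(n)]),
        elements=np.array(elements if elements is not None else ["C"] * n),
        resids=np.arange(1, n + 1),
        resnames=np.array(["RES"] * n),
        chains=np.array(["A"] * n),
        roles=np.array(roles if roles is not None else ["protein"] * n),
        charges=np.array(charges if charges is not None else [0.0] * n, dtype=float),
        rmin2=np.array(rmin2 if rmin2 is not None else [1.9] * n, dtype=float),
        epsilon=np.array(epsilon if epsilon is not None else [0.1] * n, dtype=float),
        born=np.array(born if born is not None else [1.5] * n, dtype=float),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        **flags,
    )


@pytest.fixture
def tiny_structure_factory():
    return make_structure
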