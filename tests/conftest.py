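"""Shared fixtures: force fields, topologies, and small prepared systems."""

import numpy as np
import pytest

from dpdgel.engine import state_from_configuration
from dpdgel.forcefield import build_forcefield
from dpdgel.topology import InitialConfiguration, build_nanogel


@pytest.fixture(scope="session")
def ff_ambient():
    """Default force field at 298.15 K."""
    return build_forcefield(298.15)


@pytest.fixture(scope="session")
def default_topology():
    return build_nanogel()


@pytest.fixture
def water_box_factory(ff_ambient):
    """Pure-water DPD box at reduced density 3 with seeded velocities."""

    def make(n_beads=500, seed=0):
        rng = np.random.default_rng(seed)
        box = (n_beads / 3.0) ** (1.0 / 3.0)
        init = InitialConfiguration(
            box_side=box,
            positions=rng.uniform(0.0, box, (n_beads, 3)),
            types=np.zeros(n_beads, dtype=np.int64),
            bonds=np.empty((0, 2), dtype=np.int64),
            n_polymer=0, n_water=n_beads,
        )
        return init, state_from_configuration(init, ff_ambient, seed)

    return make
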