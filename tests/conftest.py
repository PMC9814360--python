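import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from cgfep.model import (
    AlchemicalState,
    AlchemicalTopology,
    BeadType,
    Bond,
    CGSystem,
    ThermoConditions,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_charged_system(rng):
    """A random 6-bead system with charges, LJ and one bond, for invariants."""
    types = [
        BeadType("Q+", charge=1.0, lj_epsilon=2.0, lj_sigma=0.47),
        BeadType("Q-", charge=-1.0, lj_epsilon=2.0, lj_sigma=0.47),
        BeadType("N0", charge=0.0, lj_epsilon=1.5, lj_sigma=0.43),
    ]
    beads = [types[i % 3] for i in range(6)]
    pos = rng.uniform(0.5, 2.5, size=(6, 3))
    return CGSystem(
        beads=beads,
        positions=pos,
        box=np.array([3.0, 3.0, 3.0]),
        bonds=[Bond(0, 1, r0=0.5, k=500.0)],
        groups={"all": tuple(range(6))},
    )


@pytest.fixture
def charged_topology(small_charged_system):
    """Perturbs bead 2 to a dummy and halves bead 3's charge in the B state."""
    t = AlchemicalTopology.identity(small_charged_system).set_dummy_B([2])
    qB = t.charge_B.copy()
    qB[3] *= 0.5
    import dataclasses

    return dataclasses.replace(t, charge_B=qB)


@pytest.fixture
def conditions_unit_kT():
    return ThermoConditions.from_kT(1.0)


@pytest.fixture
def mid_state():
    return AlchemicalState(lambda_coul=0.6, lambda_vdw=0.3)
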