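import numpy as np
import pytest

from mpxdesign import DesignConfig, ThermoConfig
from mpxdesign.fixtures import FixtureSpec, generate_fixture

BASES = "ACGT"


def random_oligo(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    g = gc / 2.0
    a = (1.0 - gc) / 2.0
    return "".join(rng.choice(list(BASES), size=length, p=[a, g, g, a]))


@pytest.fixture(scope="session")
def default_cfg() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def thermo_cfg() -> ThermoConfig:
    return ThermoConfig()


@pytest.fixture(scope="session")
def poison_fixture():
    """A three-product poisoned fixture with exactly one feasible tiling."""
    return generate_fixture(FixtureSpec(seed=7, poison_mode=True))


@pytest.fixture(scope="session")
def random_fixture():
    """A three-product fixture on a random (unpoisoned) background."""
    return generate_fixture(FixtureSpec(seed=11))
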