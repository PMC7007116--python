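import pytest

from ferroclim import (
    STUDY_GROUPS,
    WorldConfig,
    cameroon_fixture,
    generate_world,
)
from ferroclim.disaggregation import disaggregate
from ferroclim.iron_supply import compute_iron_supply


@pytest.fixture(scope="session")
def world():
    """A small synthetic world shared by read-only tests."""
    return generate_world(WorldConfig(n_countries=12, n_foods=30, rng_seed=42))


@pytest.fixture(scope="session")
def cameroon():
    return cameroon_fixture()


@pytest.fixture(scope="session")
def world_disagg(world):
    return disaggregate(world.supply, world.catalog, world.gdd, world.energy, STUDY_GROUPS)


@pytest.fixture(scope="session")
def world_iron(world, world_disagg):
    return compute_iron_supply(world_disagg.supply, world.catalog)
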