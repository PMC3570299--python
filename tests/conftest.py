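import numpy as np
import pytest

from duoscore import (
    SimulationConfig,
    Trait,
    build_definition,
    generate_cohort,
    load_catalog,
)
from duoscore.simulate import StructureConfig


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def fg_def(catalog):
    return build_definition(catalog, Trait.FASTING_GLUCOSE)


@pytest.fixture(scope="session")
def t2d_def(catalog):
    return build_definition(catalog, Trait.T2D)


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A modest null cohort shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11, n_duos=800,
        structure=StructureConfig(n_subpops=1, n_background_snps=50),
    )
    return generate_cohort(cfg, catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
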