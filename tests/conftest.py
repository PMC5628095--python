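import numpy as np
import pytest

from urbancarbon import (
    InventoryConfig,
    generate_inventory,
    load_default_allometry,
    load_default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def allometry():
    return load_default_allometry()


@pytest.fixture(scope="session")
def small_inventory(registry):
    """1,000-tree synthetic inventory, fixed seed, shared across tests."""
    return generate_inventory(InventoryConfig(n_trees=1_000, seed=42), registry)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
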