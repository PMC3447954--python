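import numpy as np
import pytest

from cnvstress.datasets import (
    load_cnv_catalog,
    load_junction_catalog,
    load_mouse_genome,
)
from cnvstress.synthetic_data import simulate_reference


@pytest.fixture(scope="session")
def mouse_genome():
    return load_mouse_genome()


@pytest.fixture(scope="session")
def cnv_catalog(mouse_genome):
    return load_cnv_catalog(mouse_genome)


@pytest.fixture(scope="session")
def junction_catalog():
    return load_junction_catalog()


@pytest.fixture(scope="session")
def small_genome():
    """200 kb single-chromosome random genome with sequence."""
    return simulate_reference({"chrA": 200_000}, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
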