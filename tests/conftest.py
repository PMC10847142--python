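import numpy as np
import pytest

from urbanbias.datatypes import City, ModelParameters


@pytest.fixture
def two_tract_city() -> City:
    """The classic hand-checkable instance: tracts [80, 20] and [20, 80]."""
    return City("hand", np.array([[80, 20], [20, 80]]))


@pytest.fixture
def even_city() -> City:
    """Every tract at the city share: all segregation measures are zero."""
    return City("even", np.array([[60, 40], [60, 40], [60, 40]]))


@pytest.fixture
def split_city() -> City:
    """Complete segregation: single-group tracts."""
    return City("split", np.array([[100, 0], [0, 100]]))


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


def random_city(rng: np.random.Generator, max_tracts: int = 10) -> City:
    """Small random two-group city with positive tract totals and mixed groups."""
    while True:
        m = int(rng.integers(2, max_tracts + 1))
        counts = rng.integers(0, 60, size=(m, 2))
        counts[:, 1] += 1  # no empty tracts
        totals = counts.sum(axis=0)
        if totals[0] > 0 and totals[1] > 0:
            return City("rand", counts)
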