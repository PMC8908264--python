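import numpy as np
import pytest

from mobsig import City, CitySet, ODMatrix, pairwise_distances


@pytest.fixture
def toy_cities() -> CitySet:
    """Four cities on a rough north-south line in southern Finland."""
    return CitySet([
        City("A", "Alpha", 60.0, 24.0, 500_000),
        City("B", "Beta", 60.5, 24.5, 120_000),
        City("C", "Gamma", 61.5, 25.0, 40_000),
        City("D", "Delta", 63.0, 25.5, 8_000),
    ])


@pytest.fixture
def toy_dist(toy_cities):
    return pairwise_distances(toy_cities)


def make_od(period="p", **flows) -> ODMatrix:
    """Build an ODMatrix from 'A_B'=count keyword pairs."""
    return ODMatrix(period, {tuple(k.split("_")): v for k, v in flows.items()})


def random_od(rng: np.random.Generator, n_cities: int = 6,
              max_flow: int = 200, period: str = "p") -> ODMatrix:
    """Small random integer OD matrix (may include diagonal entries)."""
    ids = [f"c{i}" for i in range(n_cities)]
    flows = {}
    for o in ids:
        for d in ids:
            v = int(rng.integers(0, max_flow))
            if v:
                flows[(o, d)] = v
    return ODMatrix(period, flows)
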