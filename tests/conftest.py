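import numpy as np
import pytest

from emfi import DemandPoint, PMedianInstance, SyntheticConfig, generate_instance


@pytest.fixture
def t3():
    """3-4-5 right-triangle instance: A(0,0,w=1), B(3,0,w=2), C(0,4,w=1)."""

    def make(p: int) -> PMedianInstance:
        return PMedianInstance(
            [
                DemandPoint("A", 0.0, 0.0, 1.0),
                DemandPoint("B", 3.0, 0.0, 2.0),
                DemandPoint("C", 0.0, 4.0, 1.0),
            ],
            p=p,
        )

    return make


def random_instance(rng: np.random.Generator, n: int, p: int) -> PMedianInstance:
    """Random weighted instance on the unit square."""
    coords = rng.uniform(0, 100, size=(n, 2))
    weights = rng.uniform(0.5, 5.0, size=n)
    points = [
        DemandPoint(i, float(x), float(y), float(w))
        for i, ((x, y), w) in enumerate(zip(coords, weights))
    ]
    return PMedianInstance(points, p=p)


@pytest.fixture
def make_random_instance():
    return random_instance


@pytest.fixture(scope="session")
def small_clustered():
    """4 well-separated blobs, ~40 destinations: fast pipeline fixture."""
    config = SyntheticConfig(
        layout="clustered", total_demand=60_000, n_gen_clusters=4, seed=7
    )
    instance, labels = generate_instance(config)
    return instance, labels
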