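import random

import pytest

from molirreg import FixtureSpec, make_fixture


def seeded_random_graphs(n_graphs: int = 200):
    """Deterministic pool of small random simple graphs (n <= 15, >= 1 edge)."""
    graphs = []
    for seed in range(n_graphs):
        rng = random.Random(seed)
        n = rng.randint(4, 15)
        m = rng.randint(1, n * (n - 1) // 2)
        graphs.append(make_fixture(FixtureSpec("random_simple", (n, m), seed=seed)))
    return graphs


@pytest.fixture(scope="session")
def random_graphs():
    return seeded_random_graphs(200)
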