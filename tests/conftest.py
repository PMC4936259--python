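from pathlib import Path

import numpy as np
import pytest

from leonbis import DirichletMixture, parse_dirichlet_mixture

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_mixture() -> DirichletMixture:
    """Hand-written 3-component mixture shipped with the test suite."""
    return parse_dirichlet_mixture(DATA / "toy3.comp")


@pytest.fixture(scope="session")
def toy_mixture_path() -> Path:
    return DATA / "toy3.comp"


def random_mixture(rng: np.random.Generator, n_components: int | None = None) -> DirichletMixture:
    """Random valid mixture for property tests; informative by construction."""
    j = n_components or rng.integers(1, 5)
    weights = rng.dirichlet(np.ones(j))
    alpha = rng.gamma(shape=0.5, scale=2.0, size=(j, 20)) + 1e-3
    return DirichletMixture(weights, alpha, None)


def random_counts(rng: np.random.Generator, max_m: int = 6) -> np.ndarray:
    m = int(rng.integers(0, max_m + 1))
    counts = np.zeros(20)
    for idx in rng.integers(0, 20, size=m):
        counts[idx] += 1
    return counts
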