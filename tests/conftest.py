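import numpy as np
import pytest

from radkin import GenotypeMatrix


def hwe_genotypes(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n individuals drawn independently at Hardy-Weinberg proportions."""
    u = rng.random((n, p.shape[0]))
    g = np.zeros((n, p.shape[0]), dtype=np.int8)
    g[u < p[None, :] ** 2] = 2
    g[(u >= p[None, :] ** 2) & (u < (p**2 + 2 * p * (1 - p))[None, :])] = 1
    return g


def hwe_matrix(p: np.ndarray, n: int, rng: np.random.Generator) -> GenotypeMatrix:
    return GenotypeMatrix(
        tuple(f"s{i}" for i in range(n)),
        tuple(f"L{j}" for j in range(p.shape[0])),
        hwe_genotypes(p, n, rng),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_gm():
    """Six loci, three samples, one missing call; hand-checkable."""
    calls = np.array(
        [
            [1, 1, 2, 0, 1, 2],
            [1, 0, 2, 0, 2, 1],
            [0, 0, 1, -1, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(("a", "b", "c"), tuple(f"L{j}" for j in range(6)), calls)
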