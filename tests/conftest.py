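import numpy as np
import pytest
from hypothesis import settings

from gammasfc import (
    ConnectivityMatrix,
    SyntheticSpec,
    cohort_population_pair,
    generate_cohort,
    match_density_and_binarize,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_matrix(values, modality="structural", node_ids=None) -> ConnectivityMatrix:
    values = np.asarray(values, dtype=float)
    if node_ids is None:
        node_ids = [chr(ord("a") + i) for i in range(values.shape[0])]
    return ConnectivityMatrix(node_ids=node_ids, values=values, modality=modality)


def random_binary_pair(rng: np.random.Generator, n: int, p: float = 0.45):
    """Random symmetric binary SC/FC matrices sharing node ids."""

    def draw():
        upper = (rng.random((n, n)) < p).astype(float)
        m = np.triu(upper, k=1)
        return m + m.T

    sc = draw()
    if sc.sum() == 0:
        sc[0, 1] = sc[1, 0] = 1.0
    fc = draw()
    if fc.sum() == 0:
        fc[0, 2 % n] = fc[2 % n, 0] = 1.0
    ids = [f"n{i}" for i in range(n)]
    return (
        ConnectivityMatrix(node_ids=ids, values=sc, modality="structural", weighted=False),
        ConnectivityMatrix(node_ids=ids, values=fc, modality="functional", weighted=False),
    )


@pytest.fixture(scope="session")
def reference_spec() -> SyntheticSpec:
    """The 60-node, 4-module, 20-subject reference study."""
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def reference_cohort(reference_spec):
    return generate_cohort(reference_spec)


@pytest.fixture(scope="session")
def reference_pair(reference_cohort):
    cohort, _ = reference_cohort
    return cohort_population_pair(cohort)


@pytest.fixture()
def clique_pair():
    """SC == FC == four disjoint 5-cliques over 20 nodes."""
    n, block = 20, 5
    values = np.zeros((n, n))
    for b in range(n // block):
        ix = np.arange(b * block, (b + 1) * block)
        values[np.ix_(ix, ix)] = 1.0
    np.fill_diagonal(values, 0.0)
    ids = [f"n{i}" for i in range(n)]
    sc = ConnectivityMatrix(node_ids=ids, values=values, modality="structural", weighted=False)
    fc = ConnectivityMatrix(node_ids=ids, values=values, modality="functional", weighted=False)
    return match_density_and_binarize(sc, fc)
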