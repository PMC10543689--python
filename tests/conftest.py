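import numpy as np
import pytest

from gddclust.cohort import Individual
from gddclust.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-spec synthetic cohort shared across tests (seed 1)."""
    spec = CohortSpec(seed=1)
    return generate_cohort(spec)


@pytest.fixture()
def two_block_cohort():
    """Degenerate two-cluster cohort: penetrance 1, no background, no
    anchor — every phenotype set is exactly its cluster's marker."""
    spec = CohortSpec(
        n_individuals=40,
        n_phenotypes=4,
        n_pheno_clusters=2,
        dominant_penetrance=1.0,
        background_rate=0.0,
        gdd_anchor_rate=0.0,
        morph_rate=0.0,
        seed=5,
    )
    return generate_cohort(spec)


def random_cohort(rng: np.random.Generator, n: int, n_terms: int = 10):
    """Unstructured random cohort for property tests."""
    terms = [f"HP:R{i:02d}" for i in range(n_terms)]
    out = []
    for i in range(n):
        size = int(rng.integers(1, 5))
        chosen = rng.choice(n_terms, size=size, replace=False)
        out.append(
            Individual(id=f"P{i:03d}", phenotypes=frozenset(terms[j] for j in chosen))
        )
    return out
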