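import numpy as np
import pytest

from hodgecycles import (
    CohortSpec,
    WeightedGraph,
    build_cycle_basis,
    generate_cohort,
    generate_template,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_graph():
    """Complete graph on 8 nodes, distinct random weights."""
    return generate_template(8, seed=11)


@pytest.fixture(scope="session")
def small_basis(small_graph):
    return build_cycle_basis(small_graph)


@pytest.fixture(scope="session")
def triangle():
    """Triangle: weights 3, 2, 1 on edges (0,1), (0,2), (1,2)."""
    return WeightedGraph(n=3, w=np.array([3.0, 2.0, 1.0]))


@pytest.fixture(scope="session")
def null_cohort():
    """Small multi-site cohort with no group effect."""
    return generate_cohort(
        CohortSpec(n_nodes=10, n_subjects_per_group=24, n_sites=3, seed=5)
    )


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strong effect planted on three template cycles."""
    return generate_cohort(
        CohortSpec(
            n_nodes=12,
            n_subjects_per_group=50,
            n_sites=4,
            effect_cycles=(0, 7, 20),
            effect_size=5.0,
            seed=42,
        )
    )
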