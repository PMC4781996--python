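from __future__ import annotations

import numpy as np
import pytest

from scnet import CohortSpec, generate_cohort


def small_graphs() -> dict[str, np.ndarray]:
    """Named hand-checkable graphs used across test modules."""

    def from_edges(n, edges):
        a = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        return a

    return {
        "triangle": from_edges(3, [(0, 1), (1, 2), (0, 2)]),
        "star5": from_edges(5, [(0, i) for i in range(1, 5)]),
        "path4": from_edges(4, [(0, 1), (1, 2), (2, 3)]),
        "cycle5": from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]),
        "k4": from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
        "two_triangles": from_edges(
            6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        ),
    }


@pytest.fixture(scope="session")
def graphs() -> dict[str, np.ndarray]:
    return small_graphs()


@pytest.fixture(scope="session")
def null_cohort():
    """Exchangeable two-group cohort: no group effect of any kind."""
    return generate_cohort(
        CohortSpec(n_subjects_per_group=36, n_regions=40, n_blocks=4, seed=11)
    )


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort where group B has stronger within-block covariance."""
    return generate_cohort(
        CohortSpec(
            n_subjects_per_group=36, n_regions=40, n_blocks=4,
            r_in=0.3, group_r_in=0.7, seed=11,
        )
    )


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
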