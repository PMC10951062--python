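"""Shared fixtures: planted-structure cohorts run through the pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from omicfuse import (
    CohortSpec,
    SNFParams,
    affinity_matrix,
    complete_cases,
    generate_cohort,
    pairwise_squared_distance,
    select_k,
    snf_fuse,
    standardize,
)


@pytest.fixture(scope="session")
def planted():
    """A 300-patient cohort with two planted subgroups (effect 1.5 SD),
    carried through standardization, distances, SNF and model selection."""
    spec = CohortSpec(
        n_patients=300,
        block_sizes=(60, 120),
        n_informative=(12, 24),
        effect_size=1.5,
        seed=42,
    )
    blocks, clinical = generate_cohort(spec)
    blocks, clinical = complete_cases(blocks, clinical)
    std = [standardize(b) for b in blocks]
    distances = [pairwise_squared_distance(b) for b in std]
    params = SNFParams()
    affinities = [affinity_matrix(d, params) for d in distances]
    fused = snf_fuse(affinities, params)
    assignment = select_k(fused, 2, 6, seed=42)
    return {
        "spec": spec,
        "blocks": blocks,
        "clinical": clinical,
        "std": std,
        "distances": distances,
        "params": params,
        "affinities": affinities,
        "fused": fused,
        "assignment": assignment,
        "truth": clinical["true_subgroup"].to_numpy(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_affinity(n: int, seed: int = 0) -> np.ndarray:
    """A random valid (symmetric, positive) similarity matrix."""
    r = np.random.default_rng(seed)
    W = r.uniform(0.05, 1.0, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    return W
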