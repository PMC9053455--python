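"""Shared fixtures: small synthetic datasets and one default pipeline run."""

import logging

import numpy as np
import pandas as pd
import pytest

from paregions.scoring import classify_frame, filter_working_age, regionalize
from paregions.synthetic import (
    SimulationConfig,
    default_archetypes,
    generate_covariates,
    generate_microdata,
)
from paregions.taxonomy import ClusterSolution, build_taxonomy

logging.getLogger("paregions").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def default_run(archetypes):
    """One full default-scale synthetic run shared across test modules."""
    cfg = SimulationConfig(rng_seed=1)
    micro = generate_microdata(cfg, archetypes)
    cov = generate_covariates(cfg, archetypes)
    kept, counts = filter_working_age(micro)
    profiles = regionalize(classify_frame(kept))
    tax = build_taxonomy(profiles)
    return {
        "config": cfg,
        "microdata": micro,
        "covariates": cov,
        "profiles": profiles,
        "taxonomy": tax,
        "solution": tax.solution,
        "age_counts": counts,
    }


def make_solution(assignments: dict, labels: dict | None = None, k: int | None = None):
    """Minimal ClusterSolution for profiling/regression helpers."""
    k = k if k is not None else len(set(assignments.values()))
    return ClusterSolution(
        assignments={str(r): int(c) for r, c in assignments.items()},
        centroids=np.zeros((k, 4)),
        k=k,
        inertia=0.0,
        seed_centroids=np.zeros((k, 4)),
        n_iter=0,
        labels=labels,
    )


@pytest.fixture
def solution_factory():
    return make_solution
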