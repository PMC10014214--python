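import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import repurbench as rb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def pairwise_auroc(active_ranks, N) -> float:
    """Brute-force Mann-Whitney AUROC over all active-inactive rank pairs."""
    act = set(active_ranks)
    inact = [r for r in range(1, N + 1) if r not in act]
    if not act or not inact:
        raise ValueError("need both classes")
    wins = sum(1 for a in act for b in inact if a < b)
    return wins / (len(act) * len(inact))


def random_relevance(rng, N, n) -> rb.RelevanceVector:
    """Uniform random placement of n actives in a length-N list."""
    rel = np.zeros(N, dtype=int)
    rel[rng.choice(N, size=n, replace=False)] = 1
    return rb.RelevanceVector(tuple(rel))


@pytest.fixture(scope="session")
def small_spec():
    return rb.SyntheticSpec(
        n_drugs=80,
        n_proteins=48,
        n_indications=16,
        n_associations=160,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_universe(small_spec):
    """(standard, signature matrix, rmsd similarity) at desk-test scale."""
    standard = rb.generate_standard(small_spec)
    signatures = rb.generate_signatures(standard, small_spec)
    sim = rb.pairwise_distances(signatures, "rmsd")
    return standard, signatures, sim


@pytest.fixture(scope="session")
def disjoint_spec():
    return rb.SyntheticSpec(
        n_drugs=120,
        n_proteins=128,
        n_indications=15,
        n_associations=100,
        membership="disjoint",
        seed=5,
    )


def with_params(spec, **kw):
    return dataclasses.replace(spec, **kw)
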