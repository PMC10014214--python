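"""Random controls: hypergeometric theoretical null and empirical shuffles.

Under a uniformly random ranking, the chance that a held-out drug sees at
least one of its indication's ``n`` remaining drugs in the top ``k`` of the
``N_candidates``-long candidate list is hypergeometric:

    P(hit) = 1 − C(N_candidates − n, k) / C(N_candidates, k)

Averaging that probability over eligible indications gives the theoretical
random-control AIA, the value an empirical shuffled control converges to.

Empirical controls come in two flavors: ``shuffle_similarities`` permutes
the condensed upper triangle of a distance matrix (preserving the value
distribution while destroying all structure); ``uniform_rankings`` draws
fresh uniform random distances.  Each replicate uses its own generator
seeded at ``seed + replicate``, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from scipy.spatial.distance import squareform

from .loo import BenchmarkConfig, eligible_indications, run_loo_benchmark
from .standards import AggregateStats, AssociationStandard, MetricReport
from .signatures import SimilarityMatrix

__all__ = [
    "NullSpec",
    "hypergeometric_hit_probability",
    "expected_random_aia",
    "null_similarity",
    "run_null_control",
]

NULL_METHODS = ("shuffle_similarities", "uniform_rankings")


@dataclass(frozen=True)
class NullSpec:
    """How to build the empirical random control."""

    method: str = "uniform_rankings"
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in NULL_METHODS:
            raise ValueError(f"unknown null method {self.method!r}; expected {NULL_METHODS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def hypergeometric_hit_probability(N_candidates: int, n_actives: int, k: int) -> float:
    """P(≥ 1 of n_actives in the top k of a uniform random ordering).

    Exact rational arithmetic: 1 − C(N−n, k)/C(N, k).
    """
    if N_candidates < 1:
        raise ValueError("N_candidates must be >= 1")
    if not 0 <= n_actives <= N_candidates:
        raise ValueError("need 0 <= n_actives <= N_candidates")
    if not 1 <= k <= N_candidates:
        raise ValueError("need 1 <= k <= N_candidates")
    if n_actives == 0:
        return 0.0
    miss = Fraction(comb(N_candidates - n_actives, k), comb(N_candidates, k))
    return float(1 - miss)


def expected_random_aia(
    standard: AssociationStandard,
    cutoff: int,
    min_indication_size: int = 2,
) -> float:
    """Theoretical random-control AIA (percent) at one cutoff.

    For an indication of size s in an N-drug library, each held-out drug
    faces N − 1 candidates containing s − 1 actives; the hit probability is
    hypergeometric and identical for every drug of the indication, so the
    per-indication expected accuracy is that probability × 100.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    by_ind = eligible_indications(standard, min_indication_size)
    if not by_ind:
        raise ValueError("no indication meets min_indication_size")
    N = len(standard.drugs)
    probs = [
        hypergeometric_hit_probability(N - 1, len(drugs) - 1, min(cutoff, N - 1))
        for drugs in by_ind.values()
    ]
    return 100.0 * float(np.mean(probs))


def null_similarity(
    n_drugs: int,
    drug_ids: tuple[str, ...],
    rng: np.random.Generator,
    sim: SimilarityMatrix | None = None,
) -> SimilarityMatrix:
    """One random similarity matrix: shuffled condensed entries or fresh U(0,1)."""
    if sim is not None:
        condensed = squareform(sim.dist, checks=False)
        condensed = rng.permutation(condensed)
    else:
        condensed = rng.random(n_drugs * (n_drugs - 1) // 2)
    dist = squareform(condensed)
    return SimilarityMatrix(drug_ids=drug_ids, dist=dist)


def run_null_control(
    standard: AssociationStandard,
    config: BenchmarkConfig = BenchmarkConfig(),
    spec: NullSpec = NullSpec(),
    sim: SimilarityMatrix | None = None,
    metrics=None,
) -> MetricReport:
    """Empirical random control of the LOO benchmark (and optional metric suite).

    Per replicate r a generator seeded ``spec.seed + r`` builds a random
    similarity matrix (permuting ``sim``'s condensed entries when given and
    the method is ``shuffle_similarities``; drawing uniform distances
    otherwise), then the full benchmark runs against the real standard.
    Returns a MetricReport whose per-indication values are means across
    replicates and whose aggregate statistics describe the replicate-level
    AIA distribution.
    """
    drug_ids = tuple(standard.drugs)
    n = len(drug_ids)
    base = sim if spec.method == "shuffle_similarities" else None
    if spec.method == "shuffle_similarities" and sim is None:
        # nothing to shuffle: fall back to uniform distances, same null law
        base = None

    per_ind_acc: dict[str, dict[int, list[float]]] = {}
    rep_aia: dict[int, list[float]] = {c: [] for c in config.cutoffs}
    rep_metric: dict[str, dict[object, list[float]]] = {}
    for r in range(spec.replicates):
        rng = np.random.default_rng(spec.seed + r)
        null_sim = null_similarity(n, drug_ids, rng, base)
        result = run_loo_benchmark(standard, null_sim, config)
        for c in config.cutoffs:
            rep_aia[c].append(result.aia[c])
        for ind, acc in result.per_indication_accuracy.items():
            slot = per_ind_acc.setdefault(ind, {c: [] for c in config.cutoffs})
            for c in config.cutoffs:
                slot[c].append(acc[c])
        if metrics is not None:
            from .evaluate import run_metric_suite

            suite = run_metric_suite(standard, null_sim, config, metrics=metrics)
            for m, by_cutoff in suite.per_pair.items():
                for c, stats in by_cutoff.items():
                    rep_metric.setdefault(m, {}).setdefault(c, []).append(stats.mean)

    per_indication = {
        ind: {"indication_accuracy": {c: float(np.mean(v)) for c, v in slot.items()}}
        for ind, slot in per_ind_acc.items()
    }
    report = MetricReport.from_per_indication(per_indication)
    report.per_pair = {
        "AIA": {c: AggregateStats.of(v) for c, v in rep_aia.items()},
        **{
            m: {c: AggregateStats.of(v) for c, v in by.items()}
            for m, by in rep_metric.items()
        },
    }
    return report
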