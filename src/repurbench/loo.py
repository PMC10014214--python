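"""Leave-one-out benchmarking: hit ranks, indication accuracy, and AIA.

The protocol: for every (drug, indication) association, hold the drug out,
rank all other drugs in the library by signature similarity to it, and
record the best (smallest) rank achieved by another drug approved for the
same indication.  An association scores a *hit* at cutoff ``k`` when that
best rank is ≤ k.  Per-indication accuracy at ``k`` is the percentage of
the indication's drugs that achieve a hit; the **average indication
accuracy (AIA)** is the unweighted mean of those percentages over all
eligible indications.

Indications with fewer than ``min_indication_size`` (default 2) associated
drugs are excluded: a held-out drug from a singleton indication has no
possible active left, so it would contribute a structural zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signatures import MEASURES, SimilarityMatrix
from .standards import AssociationStandard, MetricReport, NeighborRanking

__all__ = [
    "BenchmarkConfig",
    "LooResult",
    "best_active_rank",
    "indication_accuracy",
    "run_loo_benchmark",
    "eligible_indications",
    "loo_report",
]

DEFAULT_CUTOFFS = (10, 25, 50, 100)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Rank cutoffs and filtering rules for a benchmark run."""

    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    min_indication_size: int = 2
    measure: str = "rmsd"

    def __post_init__(self) -> None:
        cutoffs = tuple(int(c) for c in self.cutoffs)
        object.__setattr__(self, "cutoffs", cutoffs)
        if not cutoffs or any(c < 1 for c in cutoffs):
            raise ValueError("cutoffs must be positive integers")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if self.min_indication_size < 2:
            raise ValueError("min_indication_size must be >= 2")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass
class LooResult:
    """Outcome of one leave-one-out benchmark run."""

    per_query: dict[tuple[str, str], int | None] = field(default_factory=dict)
    per_indication_accuracy: dict[str, dict[int, float]] = field(default_factory=dict)
    aia: dict[int, float] = field(default_factory=dict)


def best_active_rank(ranking: NeighborRanking, actives) -> int | None:
    """Smallest 1-based rank occupied by an active; ``None`` if never.

    ``actives`` must not contain the query drug (it was held out).
    """
    actives = frozenset(actives)
    if ranking.query_drug in actives:
        raise ValueError("actives must exclude the query drug")
    best = None
    for pos, drug in enumerate(ranking.ranked_drugs, start=1):
        if drug in actives:
            return pos
    return best


def indication_accuracy(loo_ranks, cutoff: int) -> float:
    """Percentage of an indication's drugs whose best active rank is ≤ cutoff.

    ``loo_ranks`` maps each associated drug to its best active rank (or
    ``None`` for a miss anywhere in the list).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if not loo_ranks:
        raise ValueError("loo_ranks must be non-empty")
    hits = sum(1 for r in loo_ranks.values() if r is not None and r <= cutoff)
    return 100.0 * hits / len(loo_ranks)


def eligible_indications(
    standard: AssociationStandard, min_indication_size: int = 2
) -> dict[str, frozenset[str]]:
    """Indication → drug set, restricted to indications of qualifying size."""
    return {
        ind: drugs
        for ind, drugs in standard.by_indication().items()
        if len(drugs) >= min_indication_size
    }


def _rank_positions(sim: SimilarityMatrix) -> np.ndarray:
    """positions[q, j] = 1-based rank of drug j in query q's ranking.

    Vectorized equivalent of calling :func:`rank_neighbors` per query; ties
    broken lexicographically by drug id.  positions[q, q] is set to N (the
    query never appears in its own list but needs a defined slot).
    """
    n = len(sim.drug_ids)
    id_rank = np.argsort(np.argsort(np.asarray(sim.drug_ids, dtype=object)))
    positions = np.empty((n, n), dtype=np.int64)
    for q in range(n):
        d = sim.dist[q].copy()
        d[q] = np.inf  # query sorts last, then dropped
        order = np.lexsort((id_rank, d))
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(1, n + 1)
        positions[q] = pos
    return positions


def run_loo_benchmark(
    standard: AssociationStandard,
    sim: SimilarityMatrix,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> LooResult:
    """Run the full leave-one-out protocol over a standard.

    Every drug in the standard must be present in the similarity matrix.
    """
    missing = sorted(set(standard.drugs) - set(sim.drug_ids))
    if missing:
        raise ValueError(f"drugs in standard missing from similarity matrix: {missing[:10]}")

    by_ind = eligible_indications(standard, config.min_indication_size)
    idx = {d: i for i, d in enumerate(sim.drug_ids)}
    positions = _rank_positions(sim)

    result = LooResult()
    for ind in sorted(by_ind):
        drugs = sorted(by_ind[ind])
        drug_idx = np.array([idx[d] for d in drugs])
        loo_ranks: dict[str, int | None] = {}
        for d, qi in zip(drugs, drug_idx):
            other = drug_idx[drug_idx != qi]
            best = int(positions[qi, other].min())
            loo_ranks[d] = best  # actives always exist (size >= 2), never None
            result.per_query[(d, ind)] = best
        result.per_indication_accuracy[ind] = {
            c: indication_accuracy(loo_ranks, c) for c in config.cutoffs
        }
    if not result.per_indication_accuracy:
        raise ValueError("no indication meets min_indication_size; nothing to benchmark")
    for c in config.cutoffs:
        vals = [acc[c] for acc in result.per_indication_accuracy.values()]
        result.aia[c] = float(np.mean(vals))
    return result


def loo_report(result: LooResult) -> MetricReport:
    """Package a LOO run as a MetricReport with 'indication_accuracy' rows."""
    per_ind = {
        ind: {"indication_accuracy": {c: v for c, v in acc.items()}}
        for ind, acc in result.per_indication_accuracy.items()
    }
    report = MetricReport.from_per_indication(per_ind)
    # AIA is by definition the aggregate mean of indication_accuracy
    return report
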