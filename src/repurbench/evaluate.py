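"""Drive the full metric suite over leave-one-out rankings.

For every eligible (drug, indication) association the held-out drug's
neighbor ranking is turned into a :class:`RelevanceVector` (actives = the
indication's remaining drugs), every requested metric is computed on it,
and the per-pair values are aggregated two ways:

* per indication — mean over the indication's pairs, then statistics over
  indications (this is what ``MetricReport.aggregate`` holds, preserving
  its mean-of-per-indication invariant);
* per pair — statistics over all pairs pooled (``MetricReport.per_pair``).

Both aggregations appear in published benchmark numbers, and they differ
on imbalanced standards, so both are always reported.
"""

from __future__ import annotations

import warnings

import numpy as np

from .classify import (
    accuracy,
    auprc,
    auroc_trapezoid,
    confusion_at_cutoff,
    f1,
    fdr,
    fpr,
    precision,
    sensitivity,
    specificity,
)
from .loo import BenchmarkConfig, eligible_indications, _rank_positions
from .rank_metrics import (
    ALPHA_RA_VALIDITY,
    DEFAULT_ALPHA,
    AlphaValidityWarning,
    EarlyRecognitionInput,
    average_precision,
    bedroc,
    enrichment_factor,
    ndcg,
)
from .signatures import SimilarityMatrix
from .standards import (
    FULL_LIST,
    AggregateStats,
    AssociationStandard,
    MetricReport,
    RelevanceVector,
)

__all__ = ["DEFAULT_METRICS", "relevance_from_positions", "run_metric_suite"]

# metric name -> (needs_cutoff, callable(rel, cutoff, alpha))
DEFAULT_METRICS = (
    "AUROC",
    "BEDROC",
    "NDCG",
    "AP",
    "EF",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "F1",
    "FDR",
    "FPR",
)

_CUTOFF_FREE = {"AUROC", "BEDROC", "AP"}


def _metric_value(name: str, rel: RelevanceVector, cutoff, alpha: float) -> float:
    if name == "AUROC":
        return auroc_trapezoid(rel)
    if name == "BEDROC":
        return bedroc(EarlyRecognitionInput.from_relevance(rel, alpha))
    if name == "AP":
        return average_precision(rel)
    if name == "AUPRC":
        return auprc(rel)
    if name == "NDCG":
        return ndcg(rel, cutoff)
    if name == "EF":
        return enrichment_factor(
            EarlyRecognitionInput.from_relevance(rel, alpha), cutoff / rel.N
        )
    c = confusion_at_cutoff(rel, cutoff)
    fn = {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "accuracy": accuracy,
        "F1": f1,
        "FDR": fdr,
        "FPR": fpr,
    }.get(name)
    if fn is None:
        raise ValueError(f"unknown metric {name!r}")
    return fn(c)


def relevance_from_positions(
    positions_row: np.ndarray, active_idx: np.ndarray, n: int, query_idx: int
) -> RelevanceVector:
    """Relevance vector of one query's (N−1)-long ranking.

    ``positions_row[j]`` is drug j's 1-based rank in the query's list (the
    query itself occupies the sentinel last slot and is dropped).
    """
    rel = np.zeros(n - 1, dtype=int)
    for j in active_idx:
        if j != query_idx:
            rel[positions_row[j] - 1] = 1
    return RelevanceVector(tuple(rel))


def run_metric_suite(
    standard: AssociationStandard,
    sim: SimilarityMatrix,
    config: BenchmarkConfig = BenchmarkConfig(),
    alpha: float = DEFAULT_ALPHA,
    metrics=DEFAULT_METRICS,
) -> MetricReport:
    """Compute every requested metric for every eligible LOO association."""
    missing = sorted(set(standard.drugs) - set(sim.drug_ids))
    if missing:
        raise ValueError(f"drugs in standard missing from similarity matrix: {missing[:10]}")
    by_ind = eligible_indications(standard, config.min_indication_size)
    if not by_ind:
        raise ValueError("no indication meets min_indication_size")
    idx = {d: i for i, d in enumerate(sim.drug_ids)}
    n = len(sim.drug_ids)
    positions = _rank_positions(sim)

    cutoffs = [c for c in config.cutoffs if c <= n - 1]
    per_indication: dict[str, dict[str, dict[object, float]]] = {}
    pooled: dict[str, dict[object, list[float]]] = {}
    if "BEDROC" in metrics:
        # one alpha-validity warning per run, not one per drug-indication pair
        worst = max(len(d) for d in by_ind.values())
        violating = sum(
            1 for d in by_ind.values() if alpha * (len(d) - 1) / (n - 1) > ALPHA_RA_VALIDITY
        )
        if violating:
            warnings.warn(
                f"alpha={alpha:g}: {violating} of {len(by_ind)} indications exceed "
                f"the BEDROC validity condition alpha*Ra <= {ALPHA_RA_VALIDITY} "
                f"(largest indication: {worst} drugs)",
                AlphaValidityWarning,
                stacklevel=2,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AlphaValidityWarning)
        _run_all(by_ind, idx, n, positions, cutoffs, metrics, alpha,
                 per_indication, pooled, config)
    per_pair = {
        m: {c: AggregateStats.of(vals) for c, vals in by_c.items()}
        for m, by_c in pooled.items()
    }
    return MetricReport.from_per_indication(per_indication, per_pair=per_pair)


def _run_all(by_ind, idx, n, positions, cutoffs, metrics, alpha,
             per_indication, pooled, config) -> None:
    for ind in sorted(by_ind):
        drug_idx = np.array(sorted(idx[d] for d in by_ind[ind]))
        pair_vals: dict[str, dict[object, list[float]]] = {}
        for qi in drug_idx:
            rel = relevance_from_positions(positions[qi], drug_idx, n, qi)
            if rel.n_actives == rel.N:
                # every candidate is active: the ranking carries no signal
                continue
            for m in metrics:
                keys = [FULL_LIST] if m in _CUTOFF_FREE else cutoffs
                for c in keys:
                    v = _metric_value(m, rel, c, alpha)
                    pair_vals.setdefault(m, {}).setdefault(c, []).append(v)
                    pooled.setdefault(m, {}).setdefault(c, []).append(v)
        per_indication[ind] = {
            m: {c: float(np.mean(vals)) for c, vals in by_c.items()}
            for m, by_c in pair_vals.items()
        }
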