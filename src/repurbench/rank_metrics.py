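"""Ranking-quality metrics: MRR, P@K, AP/MAP, EF, RIE, BEDROC, AUROC, NDCG.

Early-recognition metrics (EF, RIE, BEDROC) reward placing actives at the
very top of the list, which plain AUROC does not.  RIE is the mean
exponential rank weight of the actives divided by its expectation under a
uniform random ranking, so E[RIE] = 1 under the null.  BEDROC min–max
normalizes RIE into [0, 1] using the best case (all actives on top) and
worst case (all actives at the bottom), both evaluated by direct summation
of the same formula.

The weight parameter α controls how much of the list matters: 1/α is
roughly the fraction of the list carrying weight.  The default α = 20 is
the value most commonly used in the virtual-screening literature.  The
exponential approximation behind RIE's normalization assumes α·Ra ≪ 1
(Ra = fraction of actives); a warning is emitted when α·Ra > 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .standards import RelevanceVector

__all__ = [
    "EarlyRecognitionInput",
    "AlphaValidityWarning",
    "mean_reciprocal_rank",
    "precision_at_k",
    "average_precision",
    "mean_average_precision",
    "enrichment_factor",
    "rie",
    "rie_bounds",
    "bedroc",
    "auroc_rank_formula",
    "dcg",
    "idcg",
    "ndcg",
]

DEFAULT_ALPHA = 20.0
ALPHA_RA_VALIDITY = 0.1


class AlphaValidityWarning(UserWarning):
    """α·Ra exceeds the range where RIE's normalization is well behaved."""


@dataclass(frozen=True)
class EarlyRecognitionInput:
    """Ranks of the actives within a ranked list of N items.

    ``active_ranks`` are 1-based and distinct; ``alpha`` is the
    early-recognition weight parameter.
    """

    active_ranks: tuple[int, ...]
    N: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        ranks = tuple(int(r) for r in self.active_ranks)
        object.__setattr__(self, "active_ranks", ranks)
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if any(r < 1 or r > self.N for r in ranks):
            raise ValueError("active ranks must lie in 1..N")
        if len(set(ranks)) != len(ranks):
            raise ValueError("active ranks must be distinct")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def from_relevance(
        cls, rel: RelevanceVector, alpha: float = DEFAULT_ALPHA
    ) -> "EarlyRecognitionInput":
        return cls(active_ranks=rel.active_ranks, N=rel.N, alpha=alpha)

    @property
    def n(self) -> int:
        return len(self.active_ranks)

    @property
    def Ra(self) -> float:
        """Ratio of actives n/N."""
        return self.n / self.N

    @property
    def Ri(self) -> float:
        """Ratio of inactives 1 − n/N."""
        return 1.0 - self.Ra

    @property
    def relative_ranks(self) -> np.ndarray:
        """x_i = r_i / N."""
        return np.asarray(self.active_ranks, dtype=float) / self.N


def mean_reciprocal_rank(first_active_ranks) -> float:
    """Mean of 1/rank over queries; a ``None`` (no active found) adds 0."""
    ranks = list(first_active_ranks)
    if not ranks:
        raise ValueError("need at least one query")
    total = 0.0
    for r in ranks:
        if r is None:
            continue
        if r < 1:
            raise ValueError(f"ranks must be positive, got {r}")
        total += 1.0 / r
    return total / len(ranks)


def precision_at_k(rel: RelevanceVector, k: int) -> float:
    """Fraction of the top k that is active."""
    if not 1 <= k <= rel.N:
        raise ValueError(f"k must be in 1..{rel.N}, got {k}")
    return sum(1 for r in rel.rel[:k] if r > 0) / k


def average_precision(rel: RelevanceVector) -> float:
    """Mean of P@(rank of active) over the actives."""
    if rel.n_actives == 0:
        raise ValueError("average precision undefined with no actives")
    hits = 0
    total = 0.0
    for i, r in enumerate(rel.rel, start=1):
        if r > 0:
            hits += 1
            total += hits / i
    return total / rel.n_actives


def mean_average_precision(rels) -> float:
    rels = list(rels)
    if not rels:
        raise ValueError("need at least one relevance vector")
    return float(np.mean([average_precision(r) for r in rels]))


def enrichment_factor(inp: EarlyRecognitionInput, fraction: float) -> float:
    """Active concentration in the top ``fraction`` relative to the whole list.

    EF = (actives in top k / k) / (n/N) with k = floor(fraction × N);
    1.0 is the random expectation, N/n the maximum.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(math.floor(fraction * inp.N))
    if k < 1:
        raise ValueError(f"fraction {fraction} selects an empty top list (k=0)")
    if inp.n == 0:
        raise ValueError("enrichment factor undefined with no actives")
    hits = sum(1 for r in inp.active_ranks if r <= k)
    return (hits / k) / inp.Ra


def _rie_denominator(N: int, alpha: float) -> float:
    # expectation of exp(-alpha * r/N) over a uniform random rank r in 1..N
    return (1.0 / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)


def rie(inp: EarlyRecognitionInput) -> float:
    """Robust initial enhancement: exponentially weighted enrichment.

    RIE = (1/n) Σ_i exp(−α x_i) / [(1/N)(1 − e^(−α)) / (e^(α/N) − 1)] with
    x_i = r_i/N.  Expectation 1 under a uniform random ranking.
    """
    if inp.n == 0 or inp.n == inp.N:
        raise ValueError("RIE requires 0 < n < N")
    num = float(np.mean(np.exp(-inp.alpha * inp.relative_ranks)))
    return num / _rie_denominator(inp.N, inp.alpha)


def rie_bounds(N: int, n: int, alpha: float = DEFAULT_ALPHA) -> tuple[float, float]:
    """(RIE_min, RIE_max): actives packed at the bottom / at the top.

    Computed by direct summation of the RIE formula, not the continuous
    closed form, so the bounds are exact at finite N.
    """
    if not 0 < n < N:
        raise ValueError("bounds require 0 < n < N")
    lo = rie(EarlyRecognitionInput(tuple(range(N - n + 1, N + 1)), N, alpha))
    hi = rie(EarlyRecognitionInput(tuple(range(1, n + 1)), N, alpha))
    return lo, hi


def bedroc(inp: EarlyRecognitionInput) -> float:
    """Boltzmann-enhanced discrimination of ROC: RIE min–max scaled to [0, 1].

    Exactly 1 when the actives fill the top ranks and 0 when they fill the
    bottom ranks.  Warns when α·Ra > 0.1, outside the regime (α·Ra ≪ 1)
    where the metric is considered well behaved.
    """
    if inp.alpha * inp.Ra > ALPHA_RA_VALIDITY:
        warnings.warn(
            f"alpha*Ra = {inp.alpha * inp.Ra:.3g} > {ALPHA_RA_VALIDITY}; "
            "BEDROC is outside its stated validity regime",
            AlphaValidityWarning,
            stacklevel=2,
        )
    lo, hi = rie_bounds(inp.N, inp.n, inp.alpha)
    if hi == lo:
        raise ValueError("degenerate list: RIE_max equals RIE_min")
    return (rie(inp) - lo) / (hi - lo)


def auroc_rank_formula(inp: EarlyRecognitionInput, exact: bool = False) -> float:
    """AUROC from the mean relative rank of the actives.

    With x̄ = (1/(nN)) Σ r_i, the continuous form is
    ``(1 − x̄ − Ra/2) / Ri``.  It understates the discrete (pairwise
    Mann–Whitney) AUROC by exactly 1/(2·N·Ri) on tie-free lists; pass
    ``exact=True`` to add that correction and recover the pairwise value.
    """
    if inp.n == 0 or inp.n == inp.N:
        raise ValueError("AUROC requires 0 < n < N")
    xbar = float(np.sum(inp.active_ranks)) / (inp.n * inp.N)
    value = (1.0 - xbar - inp.Ra / 2.0) / inp.Ri
    if exact:
        value += 1.0 / (2.0 * inp.N * inp.Ri)
    return value


def _gain(rel_i: int) -> float:
    return float(2**rel_i - 1)


def dcg(rel: RelevanceVector, p: int) -> float:
    """Discounted cumulative gain over the top p ranks."""
    if not 1 <= p <= rel.N:
        raise ValueError(f"p must be in 1..{rel.N}, got {p}")
    return sum(_gain(r) / math.log2(i + 1) for i, r in enumerate(rel.rel[:p], start=1))


def idcg(rel: RelevanceVector, p: int) -> float:
    """DCG of the ideal reordering (best grades first), truncated at p."""
    if not 1 <= p <= rel.N:
        raise ValueError(f"p must be in 1..{rel.N}, got {p}")
    ideal = sorted(rel.rel, reverse=True)
    return sum(_gain(r) / math.log2(i + 1) for i, r in enumerate(ideal[:p], start=1))


def ndcg(rel: RelevanceVector, p: int) -> float:
    """DCG / IDCG in [0, 1]; defined as 0 when there are no actives."""
    denom = idcg(rel, p)
    if denom == 0.0:
        return 0.0
    return dcg(rel, p) / denom
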