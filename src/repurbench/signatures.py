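"""Pairwise interaction-signature similarity and neighbor ranking.

Two distance measures between drug signatures are supported: the root mean
squared deviation (RMSD, the default) and the cosine distance.  Smaller
distance means more similar behavior, so the most similar drug ranks first.
Signatures are compared raw — no normalization is applied before either
measure.

Ties in distance are broken lexicographically by drug identifier, which
makes every ranking total and hardware-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .standards import NeighborRanking, SignatureMatrix

__all__ = [
    "SimilarityMatrix",
    "rmsd_distance",
    "cosine_distance",
    "pairwise_distances",
    "rank_neighbors",
]

MEASURES = ("rmsd", "cosine")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix of pairwise drug–drug distances."""

    drug_ids: tuple[str, ...]
    dist: np.ndarray

    def __post_init__(self) -> None:
        dist = np.asarray(self.dist, dtype=float)
        object.__setattr__(self, "dist", dist)
        n = len(self.drug_ids)
        if dist.shape != (n, n):
            raise ValueError(f"distance matrix shape {dist.shape} != ({n}, {n})")
        if (dist < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(dist, dist.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(dist), 0.0, atol=1e-8):
            raise ValueError("distance matrix must have a zero diagonal")

    def index_of(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug {drug_id!r}") from None


def _check_pair(sig_a, sig_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(sig_a, dtype=float).ravel()
    b = np.asarray(sig_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("signatures must be non-empty")
    if a.size != b.size:
        raise ValueError(f"signature lengths differ: {a.size} vs {b.size}")
    return a, b


def rmsd_distance(sig_a, sig_b) -> float:
    """Root mean squared deviation between two signatures.

    ``sqrt(mean((a_k − b_k)^2))`` over the shared components.
    """
    a, b = _check_pair(sig_a, sig_b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cosine_distance(sig_a, sig_b) -> float:
    """Cosine distance ``1 − a·b / (|a||b|)``; range [0, 2].

    Undefined (raises) when either signature has zero norm.
    """
    a, b = _check_pair(sig_a, sig_b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm signature")
    return float(np.clip(1.0 - float(a @ b) / (na * nb), 0.0, 2.0))


def pairwise_distances(matrix: SignatureMatrix, measure: str = "rmsd") -> SimilarityMatrix:
    """All-against-all signature distances under the chosen measure."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if len(matrix.drug_ids) < 2:
        raise ValueError("need at least 2 drugs for pairwise distances")
    X = matrix.scores
    if measure == "rmsd":
        condensed = pdist(X, metric="euclidean") / np.sqrt(X.shape[1])
    else:
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = [matrix.drug_ids[i] for i in np.nonzero(norms == 0)[0]]
            raise ValueError(f"zero-norm signatures, cosine undefined: {bad[:5]}")
        condensed = np.clip(pdist(X, metric="cosine"), 0.0, 2.0)
    dist = squareform(condensed)
    np.fill_diagonal(dist, 0.0)
    return SimilarityMatrix(drug_ids=matrix.drug_ids, dist=dist)


def rank_neighbors(sim: SimilarityMatrix, query: str) -> NeighborRanking:
    """Order every non-query drug by ascending distance to the query.

    Equal distances are broken lexicographically by drug id, so the ranking
    is deterministic.
    """
    qi = sim.index_of(query)
    n = len(sim.drug_ids)
    others = np.array([j for j in range(n) if j != qi])
    dists = sim.dist[qi, others]
    # lexicographic tiebreak: sort ids once, rank them, lexsort on (rank, dist)
    id_rank = np.argsort(np.argsort(np.asarray(sim.drug_ids, dtype=object)[others]))
    order = np.lexsort((id_rank, dists))
    ordered = others[order]
    return NeighborRanking(
        query_drug=query,
        ranked_drugs=tuple(sim.drug_ids[j] for j in ordered),
        distances=sim.dist[qi, ordered],
    )
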