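"""Synthetic drug–indication standards and signature matrices.

The generator emulates the statistical shape of a curated CANDO-scale
drug–indication mapping: about two thousand drugs and indications, about
twenty thousand associations, and heavily imbalanced indication sizes —
a few indications with hundreds of associated drugs (pain, hypertension,
seizures in real mappings) against a long tail of single-digit ones.
Indication sizes are drawn from a truncated power law with exponent
``size_skew`` and renormalized to hit ``n_associations`` exactly.

Signatures carry a tunable planted signal: every indication gets a latent
protein profile, and a drug's signature is
``signal_strength × mean(profiles of its indications) + noise``.
At ``signal_strength = 0`` signatures are pure noise, independent of the
standard, so benchmark results must match the random controls; as the
signal grows, same-indication drugs become mutual nearest neighbors and
the leave-one-out accuracy approaches 100%.

That 100% limit holds only for separable clusters.  Under the default
``membership="uniform"`` assignment a drug can belong to several
indications, and its mean-mixed profile then sits at the same expected
distance from its own cluster partners as from unrelated mixtures — a
structural ambiguity, not noise, so no signal strength resolves it.  Use
``membership="disjoint"`` (one indication per drug) for the clean
planted-cluster regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .standards import AssociationStandard, SignatureMatrix

__all__ = ["SyntheticSpec", "generate_standard", "generate_signatures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark universe.

    Defaults mirror the scale of the real curated mapping the toolkit is
    modeled on: 2162 drugs, 2178 indications, 18 709 associations.
    ``n_proteins`` is the signature length (the interaction-scoring step
    that produces real signatures is out of scope, so the dimension is a
    free choice; 512 keeps full-scale generation light).
    """

    n_drugs: int = 2162
    n_proteins: int = 512
    n_indications: int = 2178
    n_associations: int = 18709
    size_skew: float = 1.6
    signal_strength: float = 1.0
    noise_sd: float = 1.0
    membership: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membership not in ("uniform", "disjoint"):
            raise ValueError("membership must be 'uniform' or 'disjoint'")
        if self.membership == "disjoint" and self.n_associations > self.n_drugs:
            raise ValueError("disjoint membership needs n_associations <= n_drugs")
        if min(self.n_drugs, self.n_proteins, self.n_indications, self.n_associations) < 1:
            raise ValueError("all counts must be positive")
        if self.n_associations < self.n_indications:
            raise ValueError("need n_associations >= n_indications (every indication gets a drug)")
        if self.n_associations > self.n_drugs * self.n_indications:
            raise ValueError("n_associations exceeds n_drugs * n_indications")
        if self.size_skew <= 0:
            raise ValueError("size_skew must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def scaled(self, factor: float) -> "SyntheticSpec":
        """A proportionally smaller universe (for desk-speed runs)."""
        return replace(
            self,
            n_drugs=max(2, round(self.n_drugs * factor)),
            n_indications=max(1, round(self.n_indications * factor)),
            n_associations=max(
                max(1, round(self.n_indications * factor)),
                round(self.n_associations * factor),
            ),
        )


def _drug_id(i: int) -> str:
    return f"d{i:05d}"


def _indication_id(i: int) -> str:
    # MeSH-like D###### identifiers (purely cosmetic, never validated)
    return f"D{100000 + i:06d}"


def _power_law_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Indication sizes: truncated power law, rescaled to sum exactly."""
    support = np.arange(1, spec.n_drugs + 1, dtype=float)
    p = support ** (-spec.size_skew)
    p /= p.sum()
    sizes = rng.choice(support.astype(int), size=spec.n_indications, p=p).astype(float)
    # rescale to the exact association budget, keeping sizes in [1, n_drugs]
    sizes *= spec.n_associations / sizes.sum()
    floor = np.floor(sizes).astype(int)
    floor = np.clip(floor, 1, spec.n_drugs)
    deficit = spec.n_associations - floor.sum()
    frac_order = np.argsort(-(sizes - np.floor(sizes)))
    i = 0
    step = 1 if deficit > 0 else -1
    guard = 0
    while deficit != 0:
        j = frac_order[i % spec.n_indications]
        new = floor[j] + step
        if 1 <= new <= spec.n_drugs:
            floor[j] = new
            deficit -= step
        i += 1
        guard += 1
        if guard > 50 * spec.n_indications:  # infeasible only if budget out of range
            raise RuntimeError("could not renormalize indication sizes")
    return floor


def generate_standard(spec: SyntheticSpec) -> AssociationStandard:
    """Draw a reproducible synthetic association standard.

    Exactly ``spec.n_associations`` unique (drug, indication) pairs; drugs
    are assigned uniformly without within-indication duplication.  All
    ``n_drugs`` drugs are listed even if some end up with no association.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _power_law_sizes(spec, rng)
    drugs = [_drug_id(i) for i in range(spec.n_drugs)]
    pairs = []
    if spec.membership == "disjoint":
        # separable planted clusters: each drug belongs to at most one indication
        pool = rng.permutation(spec.n_drugs)
        start = 0
        for j, size in enumerate(sizes):
            ind = _indication_id(j)
            pairs.extend((drugs[m], ind) for m in pool[start : start + size])
            start += size
    else:
        for j, size in enumerate(sizes):
            members = rng.choice(spec.n_drugs, size=size, replace=False)
            ind = _indication_id(j)
            pairs.extend((drugs[m], ind) for m in members)
    return AssociationStandard.from_pairs(pairs, drugs=drugs)


def generate_signatures(
    standard: AssociationStandard, spec: SyntheticSpec
) -> SignatureMatrix:
    """Signatures with a planted indication signal.

    Each indication gets an i.i.d. standard-normal latent profile; a drug's
    signature is the unweighted mean of its indications' profiles scaled by
    ``signal_strength``, plus N(0, noise_sd²) noise.  Drugs without any
    indication are pure noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n_prot = spec.n_proteins
    ind_index = {ind: i for i, ind in enumerate(standard.indications)}
    profiles = rng.standard_normal((len(ind_index), n_prot))
    drug_inds: dict[str, list[int]] = {d: [] for d in standard.drugs}
    for d, i in standard.associations:
        drug_inds[d].append(ind_index[i])
    scores = rng.standard_normal((len(standard.drugs), n_prot)) * spec.noise_sd
    if spec.signal_strength > 0:
        for r, d in enumerate(standard.drugs):
            idx = drug_inds[d]
            if idx:
                scores[r] += spec.signal_strength * profiles[idx].mean(axis=0)
    return SignatureMatrix(tuple(standard.drugs), tuple(f"p{k:05d}" for k in range(n_prot)), scores)
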