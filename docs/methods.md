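# Methods

## The benchmark model

The toolkit evaluates similarity-based drug repurposing: each drug is a
vector of interaction scores against a protein library (its *signature*),
and the working hypothesis is that drugs with similar signatures treat
similar indications.  The evaluation never looks at the signatures'
biological content; it only asks whether signature *distance* predicts
shared membership in a curated drug–indication standard.

Two distances are implemented, applied to raw signatures with no
normalization: RMSD `sqrt(mean((a−b)²))` (the default) and cosine distance
`1 − a·b/(|a||b|)`.  Ranks are 1-based everywhere.  Ties in distance are
broken lexicographically by drug identifier, which makes every ranking a
total order and all results hardware-independent; with continuous
synthetic scores ties essentially never occur, so the rule is a
determinism guarantee rather than a modeling choice.

### Leave-one-out protocol

For every association (d, i) where indication i has at least
`min_indication_size` (default 2) drugs, drug d is held out and the other
N−1 drugs are ranked by distance to it.  The best rank achieved by another
drug of i is recorded; per-indication accuracy at cutoff k is the
percentage of i's drugs whose best rank is ≤ k, and AIA(k) is the
*unweighted* mean over eligible indications (a deliberately
indication-centric average: a 200-drug indication counts the same as a
3-drug one).  Indications with a single drug are excluded because their
held-out drug has no possible active left — including them would add a
structural zero that says nothing about the method.

### Random controls

Under a uniformly random ranking the probability that a held-out drug of an
indication with s drugs scores a top-k hit is hypergeometric:

    P(hit) = 1 − C(N−1−(s−1), k) / C(N−1, k)

computed in exact rational arithmetic (`math.comb` + `Fraction`).  The mean
of this probability over eligible indications, ×100, is the theoretical
null AIA.  Empirical controls rebuild a random similarity matrix per
replicate — either by permuting the condensed upper triangle of the real
matrix (preserving the distance distribution, destroying all structure) or
by drawing fresh uniform distances — and rerun the entire benchmark.
Replicate r uses a generator seeded `seed + r`, so any replicate is
reproducible in isolation.  The null-control runner accepts an optional
similarity matrix; without one, the shuffle method falls back to uniform
distances, which induces the same uniform-ranking law.

### Metric conventions

* **RIE** uses the continuous normalization
  `(1/N)(1−e^(−α))/(e^(α/N)−1)` for the random expectation, the form that
  makes E[RIE] = 1 under a uniform random ranking (verified by Monte Carlo
  in the tests, and identical to the rdkit reference implementation).
* **BEDROC** normalizes RIE by bounds computed by *direct summation* with
  all actives packed at the top/bottom, so BEDROC is exactly 1 and 0 in
  the extreme cases at any finite N.  (Closed-form continuous bounds, as
  some implementations use, differ by O(1/N).)  A warning fires when
  α·Ra > 0.1, outside the α·Ra ≪ 1 regime where the metric is considered
  well behaved; the suite driver condenses this to one warning per run
  because large indications always violate it at the default α = 20.
* **Rank-formula AUROC**: with x̄ = Σr_i/(nN), the continuous form
  `(1 − x̄ − Ra/2)/Ri` understates the discrete pairwise Mann–Whitney
  AUROC by exactly 1/(2N·Ri) on tie-free lists (derivation: the exact
  identity is `1 − (x̄ − (n+1)/(2N))/Ri`; replacing (n+1)/(2N) by Ra/2
  drops 1/(2N)).  Both forms are exposed (`exact=True` adds the
  correction); the trapezoid AUROC over the per-cutoff ROC points equals
  the pairwise statistic exactly and is what the metric suite reports.
* **AUPRC** uses step interpolation (precision-weighted recall
  increments), which equals average precision on binary labels; linear PR
  interpolation is known to overestimate and is not offered.
* **NDCG** uses gain (2^rel − 1)/log2(rank+1); binary grades by default,
  integer grades supported.  NDCG of a list with no actives is defined as
  0.
* Metrics with a zero denominator raise `UndefinedMetricError` rather than
  returning 0 — silent zeros corrupt aggregates.  The one exception is F1,
  computed as `2·TP/(2·TP+FP+FN)`: this algebraically equivalent form is
  defined whenever at least one active or positive call exists, which is
  what published mean-F1 numbers over sparse standards implicitly assume
  (most pairs have TP = 0 and contribute 0, not "undefined").

### Aggregation

Per-query relevance vectors are aggregated two ways and both are always
reported: per indication (mean over the indication's queries, then
statistics over indications — this is the `aggregate` field, and its mean
is by construction the mean of per-indication values) and per pair (all
queries pooled — the `per_pair` field).  On imbalanced standards the two
differ; neither is privileged.  Queries whose entire candidate list is
active (an indication spanning the whole library) are skipped in the
metric suite: no inactive exists, so discrimination metrics are undefined
and the ranking carries no information.

## Synthetic data

The generator emulates the statistical shape of a large curated mapping:
defaults are 2162 drugs, 2178 indications, 18 709 associations.  Indication
sizes are drawn from a truncated power law `p(s) ∝ s^(−size_skew)` on
1..n_drugs and rescaled to hit the association budget exactly (largest
fractional parts rounded up first, sizes clipped to [1, n_drugs]).  The
default exponent 1.6 reproduces the qualitative contrast of real standards
— a handful of indications with hundreds of drugs against a long tail of
twos and threes.  When the budget is far from the law's own expected total
the rescaling flattens or sharpens the realized distribution; exponent
recovery is therefore only tested at matched budgets.

Signatures: each indication receives an i.i.d. standard-normal latent
protein profile of length `n_proteins` (default 512 — the signature
dimension is free here, since the interaction-scoring step that would fix
it is out of scope, and rank statistics are insensitive to it); a drug's
signature is `signal_strength × mean(profiles of its indications)` plus
`N(0, noise_sd²)` noise.  Drugs with no indication are pure noise.
Defaults `signal_strength = 1`, `noise_sd = 1` put the benchmark in an
informative-but-far-from-saturated regime.

**Membership modes.**  With the default `membership="uniform"`, drugs are
assigned to each indication uniformly without within-indication
duplication, so multi-indication drugs arise naturally.  Mean-mixing their
profiles has a structural consequence worth spelling out: a drug belonging
to indications {A, B} has expected squared distance `p/2·signal²` both to
a pure-A partner *and* to an unrelated orphan or mixture — so its own
actives are not favored no matter how strong the signal, and AIA saturates
below 100%.  This is a faithful model of cross-indication leakage, not a
bug.  `membership="disjoint"` partitions drugs (one indication each) and
yields the clean separable-cluster regime in which AIA provably reaches
100% as signal grows; the parameter-recovery tests use it for exactly that
reason.

What the generator does *not* model: real interaction-score distributions
(docking scores are non-Gaussian and column-correlated), chemical-series
redundancy ("me too" drugs), correlated indications (disease hierarchies),
or biased curation.  Passing tests therefore demonstrate the correctness
of the evaluation machinery and its null calibration, not the performance
of any real repurposing platform.

## Problem sizes

The shipped tests and examples run at reduced scale chosen for quick
desk iteration: universes of 80–500 drugs, null controls with 20–30
shuffle replicates, 1,000–10,000 Monte-Carlo instances for the metric
expectations, and the exhaustive rank-formula/pairwise AUROC identity on
all tie-free instances up to N = 12 plus 200 random instances up to
N = 2000.  All scale parameters are plain function arguments; nothing in
the machinery depends on these sizes.

## Known limitations

* The AIA exclusion rule for singleton indications is this toolkit's
  documented choice; published AIA values from other platforms may treat
  them differently.
* BEDROC values computed with different α, or on standards of very
  different density, are not comparable; the α·Ra warning marks the cases
  where even a single α is problematic.
* The two-column TSV mapping dialect and the signature-matrix TSV header
  format are this toolkit's conventions, chosen for bit-exact round trips;
  they are not an interchange standard.
* MCC is exposed as a function but not included in the default suite
  metric set, because its marginals are frequently degenerate at small
  cutoffs on sparse standards (it raises rather than fabricating a 0).
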