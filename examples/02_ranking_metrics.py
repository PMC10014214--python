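"""The ranking-metric zoo on one ranked list.

A single ranking of 1,000 candidates with 5 actives concentrated near the
top — the sparse regime (few known treatments in a large library) that
drug-indication standards live in.  Early-recognition metrics (EF, RIE,
BEDROC) reward that concentration far more than plain AUROC does, which is
why they are preferred for screening-style evaluations.
"""

import repurbench as rb
from repurbench.rank_metrics import EarlyRecognitionInput

# actives at these 1-based ranks; everything else inactive
active_ranks = (1, 2, 5, 13, 34)
N = 1000
rel = rb.RelevanceVector(tuple(1 if i + 1 in active_ranks else 0 for i in range(N)))
inp = EarlyRecognitionInput(active_ranks, N, alpha=20.0)

print(f"N={N}, {len(active_ranks)} actives at ranks {active_ranks}")
print(f"P@10        {rb.precision_at_k(rel, 10):.3f}")
print(f"AP          {rb.average_precision(rel):.3f}")
print(f"EF(1%)      {rb.enrichment_factor(inp, 0.01):.2f}   (1.0 = random)")
print(f"RIE         {rb.rie(inp):.2f}   (1.0 = random)")
print(f"BEDROC      {rb.bedroc(inp):.3f}  (0..1)")
print(f"AUROC       {rb.auroc_rank_formula(inp, exact=True):.3f}  (0.5 = random)")
print(f"NDCG@10     {rb.ndcg(rel, 10):.3f}")
print("\nBEDROC and EF reward the early pile-up of actives; AUROC alone")
print("would judge a late-but-even spread almost as favorably.")
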