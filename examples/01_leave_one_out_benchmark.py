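"""Leave-one-out benchmark on a small synthetic drug library.

Generates a 200-drug universe with planted indication signal, ranks every
drug's neighbors by interaction-signature RMSD, and scores how often a
held-out drug finds another drug of its indication within the top ranks.
The average indication accuracy (AIA) is compared with the hypergeometric
random expectation: the gap is the recovered signal.
"""

import repurbench as rb

spec = rb.SyntheticSpec(
    n_drugs=200, n_proteins=64, n_indications=40, n_associations=400,
    signal_strength=2.0, seed=42,
)
standard = rb.generate_standard(spec)
signatures = rb.generate_signatures(standard, spec)
similarity = rb.pairwise_distances(signatures, "rmsd")

config = rb.BenchmarkConfig(cutoffs=(10, 25, 50, 100))
result = rb.run_loo_benchmark(standard, similarity, config)

print(f"{standard.n_associations} associations, "
      f"{len(standard.drugs)} drugs, {len(standard.indications)} indications")
print("cutoff  AIA      random expectation")
for c in config.cutoffs:
    print(f"top{c:<5} {result.aia[c]:6.1f}%  {rb.expected_random_aia(standard, c):6.1f}%")
print("\nAIA above the random line at every cutoff means signature similarity")
print("recovers the planted drug-indication structure.")
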