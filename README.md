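# repurbench

A benchmarking toolkit for **drug-repurposing rankings**: given a library of
drugs characterized by proteomic interaction signatures and a curated
drug–indication "gold standard", it measures how well signature similarity
recovers known therapeutic associations — and how much of that recovery
would be expected by chance.

Drug-repurposing platforms rank every drug against every other by the
similarity of their interaction signatures, on the premise that drugs with
similar proteome-wide behavior can treat the same indications.  Evaluating
such rankings rigorously requires a whole family of metrics, each with
blind spots, plus matched random controls.  `repurbench` implements the
full pipeline on reproducible synthetic data, for methods developers who
need a trustworthy yardstick rather than a particular curated database.

## What it computes

**Leave-one-out benchmark (AIA).**  For every association (d, i), drug *d*
is held out and all other drugs are ranked by signature distance (RMSD by
default, cosine optionally; ties broken lexicographically).  The
association scores a hit at cutoff *k* if another drug of indication *i*
appears at rank ≤ *k*.  Per-indication accuracy is the percentage of the
indication's drugs achieving a hit; the **average indication accuracy** is
the unweighted mean over indications:

    AIA(k) = (1/|I|) Σ_i  100 · |{d ∈ D_i : bestrank(d, i) ≤ k}| / |D_i|

**Ranking metrics.**  MRR, P@K, AP/MAP, enrichment factor
EF = (hits@k / k)/(n/N), robust initial enhancement

    RIE = (1/n) Σ_i exp(−α·r_i/N)  /  [(1/N)(1−e^(−α))/(e^(α/N)−1)]

with E[RIE] = 1 under a random ranking, BEDROC = (RIE − RIE_min)/(RIE_max −
RIE_min) ∈ [0, 1], the rank-formula AUROC (1 − x̄ − Ra/2)/Ri with its exact
discrete correction +1/(2N·Ri) that recovers the Mann–Whitney statistic,
and DCG/IDCG/NDCG with binary or graded relevance.

**Classification metrics.**  Confusion counts at any rank cutoff;
sensitivity, specificity, FDR, FPR, precision, accuracy, F1, MCC (undefined
denominators raise, they never silently return 0); ROC curves with
trapezoid AUROC; PR curves with step-interpolated AUPRC (≡ average
precision on binary labels).

**Random controls.**  The closed-form hypergeometric probability that a
held-out drug sees ≥ 1 of its indication's n remaining drugs in a random
top-k, `1 − C(N−n, k)/C(N, k)`, averaged into a theoretical null AIA; and
empirical controls that shuffle the distance matrix or draw uniform
rankings and rerun everything.

**Synthetic data.**  Standards with power-law (heavy-tailed) indication
sizes — a few indications with hundreds of drugs against a long tail of
single-digit ones — and signature matrices with a tunable planted signal,
so that recovery can be dialed from pure noise to perfect.

## Worked example

`examples/01_leave_one_out_benchmark.py` builds a 200-drug universe with a
planted signal and benchmarks it:

```
400 associations, 200 drugs, 40 indications
cutoff  AIA      random expectation
top10      73.6%    35.2%
top25      86.6%    54.4%
top50      93.5%    72.1%
top100     97.8%    88.1%
```

AIA sits above the hypergeometric random line at every cutoff: signature
similarity recovers the planted drug–indication structure.  For a single
indication the arithmetic is the classic worked case: 58 associated drugs
of which 23 achieve a top-10 hit give a top-10 indication accuracy of
23/58 × 100 = 39.6%.

The other examples show the ranking-metric zoo on one list
(`02_ranking_metrics.py`), empirical-versus-theoretical nulls
(`03_random_controls.py`, agreeing within Monte-Carlo error), and the
ten-drug mock classification (`04_classification_metrics.py`: TP=3, FP=2,
TN=4, FN=1 at cutoff 5, giving sensitivity 0.750, precision 0.600,
accuracy 0.700, F1 0.667).

A thin CLI wraps the same library:

```sh
repurbench simulate --n-drugs 200 --out data/
repurbench benchmark --standard data/standard.tsv --signatures data/signatures.tsv --out bench/
repurbench null --standard data/standard.tsv --replicates 20 --out null/
repurbench report --report bench/loo_report.json --out report/
```

Every run writes a `provenance.json` (config echo, seed, version) so any
output can be regenerated byte-for-byte.

## Layout

- `src/repurbench/standards.py` — data model and TSV/JSON readers/writers
- `src/repurbench/signatures.py` — RMSD/cosine distances, neighbor ranking
- `src/repurbench/loo.py` — leave-one-out protocol, indication accuracy, AIA
- `src/repurbench/rank_metrics.py` — MRR, P@K, AP, EF, RIE, BEDROC, AUROC, NDCG
- `src/repurbench/classify.py` — confusion metrics, ROC/PR curves
- `src/repurbench/nulls.py` — hypergeometric theory and shuffled controls
- `src/repurbench/synthetic.py` — standard and signature generators
- `src/repurbench/evaluate.py` — metric suite over all LOO rankings
- `src/repurbench/cli.py` — `repurbench` command-line driver

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
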