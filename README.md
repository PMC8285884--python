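# mscfs — multi-source circRNA functional similarity

Circular RNAs (circRNAs) are covalently closed non-coding RNAs whose
functions are mostly unannotated, so "how functionally similar are two
circRNAs?" cannot be answered from any single database. `mscfs` infers a
circRNA–circRNA functional similarity network by combining three
independent evidence channels and calibrating their mixture against an
external reference signal. It is aimed at computational biologists who
prioritise circRNA candidates for disease association, sponge-function or
co-regulation studies.

## The model

Three similarity matrices over a common set of circRNAs are computed and
fused as a convex combination

```
FS = α·CDFS + β·GOFS + γ·SQFS,        α + β + γ = 1
```

* **CDFS** (disease channel). Diseases live in a MeSH-style DAG. A disease
  *D* assigns each ancestor *d* a contribution
  `D_D(D) = 1`, `D_D(d) = max{Δ·D_D(d′) : d′ child of d}` with semantic
  contribution factor Δ (default 0.5), and a semantic value
  `DV(D) = Σ_d D_D(d)`. Two diseases score
  `S(M,N) = Σ_{d∈T_M∩T_N}(D_M(d)+D_N(d)) / (DV(M)+DV(N))`, and two
  circRNAs score the best-match average of their annotated disease sets.
* **GOFS** (ontology channel). Ontology axioms (`is_a`, `relationship`
  lines of an OBO file), gene→GO annotations and circRNA→gene links are
  rendered as three-token sentences (`gene has-function GO:…`); a
  skip-gram model with negative sampling (sg=1, size=200, window=10,
  iter=5, negative=4, min_count=1) embeds every entity; gene–gene
  similarity is the clamped cosine of the vectors, and circRNA pairs score
  the best-match average over their gene sets.
* **SQFS** (sequence channel). Each sequence is mapped into the unit
  square by the chaos game (`P_i = 0.5·(P_{i−1}+S_i)` with A=(0,0),
  C=(1,0), G=(1,1), U=(0,1)), binned on a 2^s×2^s grid (s=3), and each
  cell contributes its x-sum, y-sum and count z-score to a 192-dimensional
  feature vector; similarity is the absolute Pearson correlation of the
  vectors.

The weights are tuned by grid search (step 0.1, α ≤ 0.2, 30 combinations)
maximising the Pearson correlation between FS and **CMS**, the Jaccard
similarity of the miRNA sets bound by each circRNA pair — an independent
signal grounded in the miRNA-sponge role of circRNAs. The fused network
is evaluated against co-expression similarity (absolute Pearson of
expression profiles, unbinned and after binning pairs by FS in steps of
0.1) and exported as an edge list above a similarity cutoff (default 0.7).

A synthetic-data module generates all inputs (disease DAG, OBO ontology,
annotation tables, FASTA sequences, miRNA links, expression profiles) with
planted cluster structure, so the entire method is testable offline.

## Worked example

`python examples/full_pipeline.py` generates a 30-circRNA dataset with two
planted clusters (5% noise), builds all three networks, tunes the weights
and evaluates the fusion:

```
30 circRNAs in 2 planted clusters
tuned weights over 30 combinations: alpha=0.2, beta=0.5, gamma=0.3
fused similarity vs miRNA Jaccard: R=0.978, P=2.31e-298, 435 pairs
binned co-expression correlation:  R=0.973, 4 occupied bins
functional similarity network at cutoff 0.7: 266 edges
```

The tuned fused network correlates strongly with both held-out signals
because the generator plants exactly the cluster structure the three
channels measure; the 435 pairs are the strict upper triangle of the
30×30 matrix. The other scripts in `examples/` demonstrate each channel
in isolation (`disease_similarity.py`, `ontology_embedding.py`,
`sequence_cgr.py`) and the weight-recovery experiment
(`weight_tuning.py`).

A thin CLI wraps the same functions for shell use:

```sh
mscfs simulate --seed 5 --out-dir data/
mscfs cdfs --dag data/disease_dag.tsv --assoc data/circ_disease.tsv --out cdfs.tsv
mscfs tune --cdfs cdfs.tsv --gofs gofs.tsv --sqfs sqfs.tsv --cms cms.tsv
mscfs run-all --config run.yaml --out-dir results/
```

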