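# Methods

## Overview

`mscfs` estimates circRNA–circRNA functional similarity by fusing three
independent similarity networks — disease-semantic (CDFS),
ontology-embedding (GOFS) and sequence chaos-game (SQFS) — with convex
weights tuned against circRNA–miRNA association similarity (CMS). This
note records the model assumptions, the parameters that matter, the
numerical conventions, and what the synthetic-data experiments do and do
not demonstrate.

## Disease channel (CDFS)

Diseases form a DAG (MeSH-style: nodes are headings, child→parent edges
are broader-than relations). For a query disease the contribution of each
ancestor decays by the semantic contribution factor Δ per hop along the
best path, via the recursion `D_D(D)=1`,
`D_D(d)=max{Δ·D_D(d′): d′ child of d within the ancestor closure}`; this
equals Δ raised to the shortest hop count, which the test suite verifies
against a brute-force path-enumeration oracle. Pairwise disease
similarity normalises the shared-ancestor mass by the two semantic
values; circRNA similarity is the best-match average over annotated
disease sets.

Choices:

* **Δ = 0.5 by default**, the convention of Wang-style DAG measures;
  exposed as a parameter. Similarity between unrelated diseases decays to
  0 as Δ→0 (property-tested).
* **Multiple DAG positions** of one disease are merged into a single
  ancestor closure over all parent edges.
* **Empty disease sets.** The pairwise formula divides by |D(i)|+|D(j)|;
  when either set is empty the off-diagonal entry is the missing sentinel
  (NA), not 0 — absence of evidence is not dissimilarity, and fusion can
  renormalise over the remaining channels. Diagonals are always exactly 1.

## Ontology channel (GOFS)

The corpus renders each ontology axiom, each gene→GO annotation and each
circRNA→gene link as one three-token sentence
(`subject relation object`), with annotations connected by the
`has-function` keyword. Sentences are ordered deterministically: axioms in
file order, then annotations sorted lexicographically. With window 10,
every token of a sentence is in every other token's context.

The trainer is a compact word2vec-style skip-gram with negative sampling:
input vectors initialised uniformly in ±0.5/size, output vectors at zero,
one positive and `negative` noise tokens per context pair, noise drawn
from the unigram^0.75 distribution, learning rate decaying linearly from
0.025 to 1e-4 over all epochs. Defaults follow the word2vec parameter
names: sg=1, min_count=1, size=200, window=10, iter=5, negative=4.
Training is single-pass-per-epoch in fixed sentence order with one seeded
generator, so a fixed (corpus, config, seed) reproduces vectors exactly.
CBOW (sg=0) is accepted in the config but not trained.

Gene–gene similarity is the cosine of the two vectors clamped to [0, 1]
(negative cosines carry no usable "anti-function" signal and would break
the similarity contract). CircRNA similarity is the best-match average
over gene sets, mirroring the disease channel; the set aggregation uses
max by analogy with the disease-set rule. circRNA tokens do receive
trained vectors (they appear in the corpus) and are exposed for
inspection, but circRNA similarity is computed from gene sets, which is
the better-grounded formula. Genes without vectors are dropped with a
warning; empty effective gene sets yield NA.

On small corpora the embedding signal is real but modest: within-group
versus between-group mean cosine gaps of order 1e-2 to 1e-3. Tests
therefore assert the ordering of means over many pairs and allow 1 of 5
seeds to fail, not per-pair margins.

## Sequence channel (SQFS)

The chaos game maps a sequence into the open unit square: from
P₀ = (0.5, 0.5), each nucleotide moves the point halfway toward its
vertex (A lower-left, C lower-right, G upper-right, U upper-left). T is
read as U (inputs are DNA-alphabet); N and other IUPAC ambiguity codes
are skipped without moving the point, keeping the trajectory
deterministic. P₀ itself is not binned — it carries no sequence
information.

The trajectory is binned on a 2^s×2^s grid (default s=3, 64 cells),
half-open cells [k/2^s, (k+1)/2^s) with the top/right border clamped
inward, row-major by (y-cell, x-cell). Each cell contributes
(X_i, Y_i, Z_i): the x- and y-coordinate sums of its points and the
z-score of its point count over all cells (population standard deviation;
all-equal counts give all-zero z-scores). The feature vector concatenates
the per-cell triples: length 3·4^s = 192 at s=3. Binning conserves
counts and coordinate sums exactly (tested on random sequences against an
independent per-point binning oracle).

Similarity is the **absolute Pearson correlation** of two feature vectors
by default; a cosine variant (dot product over norms, clamped at 0) is
available via `metric="cosine"`. Both keep [0, 1]. Zero-variance feature
vectors make Pearson undefined; such entries become NA with a warning.
The grid convention (cell ordering, boundary handling) is fixed for
bit-exact reproducibility; any consistent convention gives the same
similarities.

## Fusion, tuning and evaluation

`FS = α·CDFS + β·GOFS + γ·SQFS` with α, β, γ ≥ 0 summing to 1 (within
1e-9). Where a channel is NA for a pair, the remaining weights are
renormalised over the available channels, keeping FS on [0, 1]; a strict
mode propagates NA instead. Diagonals are forced to 1.

CMS is the Jaccard index of the miRNA sets bound by two circRNAs; pairs
where both sets are empty are NA. Correlations between similarity
matrices use strictly-upper-triangle pairs defined in both matrices
(self-pairs are identically 1 and would inflate r), require at least 3
usable pairs, and report (r, p, n_pairs).

The grid search enumerates α ∈ {0, step, …, α_max},
β ∈ {0, step, …, 1}, γ = 1−α−β ≥ 0; with step 0.1 and α_max 0.2 this is
exactly 30 combinations. α is capped low because disease evidence is the
sparsest channel. The argmax by r breaks ties by smaller p, then
lexicographic (α, β) — fixed for determinism.

Expression evaluation computes pairwise co-expression similarity as the
absolute Pearson correlation of expression profiles, optionally buckets
pairs by FS into bins [k·step, (k+1)·step), and correlates per-bin mean
FS with per-bin mean expression similarity; empty bins are dropped and
fewer than two occupied bins is an error. The cutoff network keeps all
pairs with FS ≥ cutoff (inclusive), excluding NA and the diagonal,
sorted by descending score.

## Synthetic data

The generator plants `n_clusters` functional clusters across `n_circ`
circRNAs and emulates every input format: a rooted disease tree
(depth 4, branching 2 by default) with each cluster anchored in its own
root branch; a GO-style is_a hierarchy (62 terms, depth 4) with a few
part_of relations, each cluster annotating its genes inside one branch;
cluster-ancestor sequences (200–500 nt) with i.i.d. point substitutions
at the `noise` rate (no indels — substitution-level divergence is all the
chaos-game features need); per-cluster miRNA pools shared by all members;
and expression profiles equal to a cluster mean plus Gaussian noise with
standard deviation `noise` over 10 samples. `noise` is also the
per-element corruption probability for the association tables. Everything
derives from one seeded generator: identical config + seed gives
byte-identical files.

Defaults (30 circRNAs, 40 diseases, 40 genes, 62 GO terms, 40 miRNAs,
3 clusters, noise 0.1) are desk-scale stand-ins for the hundreds of
circRNAs real studies use; they keep the full pipeline under a few
seconds while leaving every statistic well-defined (435 pairs at n=30).

What passing on synthetic data shows: the formulas are implemented
correctly, the channels each recover planted co-function signal, and the
grid search recovers known mixing weights under small noise. What it does
not show: performance on real databases, where disease annotation is far
sparser, ontology corpora are ~10^5 sentences, sequences diverge by
indels and rearrangements, and the channels are not conditionally
independent given function.

## Numerical conventions and degenerate inputs

* Similarity matrices are validated on construction: symmetry within
  1e-9, entries in [0, 1] or NA, diagonal 1 or NA. Serialisation is TSV
  with `NA` sentinels; round-trips preserve values to 1e-9 (in practice
  exactly, via repr-precision floats).
* Identifier normalisation trims and collapses internal whitespace; case
  is preserved (MeSH headings are case-significant). The package expects
  circRNA identifiers already reconciled across sources; alias resolution
  is out of scope.
* Zero-variance inputs raise (correlation) or yield NA with a warning
  (feature vectors) rather than returning NaN silently.
* Weight-grid arithmetic uses integer multiples of the step to avoid
  floating-point drift in the α+β+γ=1 constraint.

## Known limitations

* The ontology trainer is a minimal SGNS: no dynamic window shrinkage, no
  frequent-token subsampling, single-threaded. Adequate for the corpus
  sizes here; for 10^5+ sentence corpora a dedicated embedding library
  would be faster.
* The OBO reader covers [Term] stanzas with id/name/is_a/relationship and
  obsolete flags — the subset the corpus needs — not full OBO 1.4.
* CDFS treats all disease annotations as equally reliable; no evidence
  weighting.
* Expression evaluation assumes profiles over identical samples; no
  batch correction.
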