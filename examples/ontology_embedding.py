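"""Skip-gram embeddings of an ontology corpus and the GOFS matrix.

Builds a toy GO-style hierarchy with two disjoint branches, annotates two
groups of genes to opposite branches, trains entity vectors on the
axiom + annotation corpus, and shows that on average genes sharing a
branch embed closer together than genes from different branches, and that
this propagates to circRNA similarity (GOFS).
"""

import itertools

import numpy as np

from mscfs import (
    AssociationTable,
    OntologyGraph,
    Word2VecConfig,
    build_corpus,
    gene_similarity,
    gofs_matrix,
    train_embeddings,
)

# two disjoint is_a chains play the role of unrelated GO branches
branch_a = [f"GO:A{i}" for i in range(8)]
branch_b = [f"GO:B{i}" for i in range(8)]
axioms = [(branch_a[i], "is_a", branch_a[i - 1]) for i in range(1, 8)]
axioms += [(branch_b[i], "is_a", branch_b[i - 1]) for i in range(1, 8)]
ontology = OntologyGraph(terms=frozenset(branch_a + branch_b), axioms=axioms)

genes_a = [f"geneA{i}" for i in range(6)]
genes_b = [f"geneB{i}" for i in range(6)]
gene_go = AssociationTable.from_pairs("gene-go",
    [(g, t) for g in genes_a for t in branch_a[1:]]
    + [(g, t) for g in genes_b for t in branch_b[1:]])
circ_gene = AssociationTable.from_pairs("circ-gene", [
    ("circA", genes_a[0]), ("circA", genes_a[1]),
    ("circB", genes_b[0]), ("circB", genes_b[1]),
    ("circAB", genes_a[0]), ("circAB", genes_b[0]),
])

corpus = build_corpus(ontology, gene_go, circ_gene)
print(f"corpus: {len(corpus)} sentences, e.g. {corpus.sentences[0]}")

# a corpus this small needs more epochs than the large-corpus default of 5
emb = train_embeddings(corpus, Word2VecConfig(size=16, iter=50), seed=42)
within = np.mean([gene_similarity(emb, a, b)
                  for g in (genes_a, genes_b)
                  for a, b in itertools.combinations(g, 2)])
between = np.mean([gene_similarity(emb, a, b)
                   for a in genes_a for b in genes_b])
print(f"mean cosine, genes sharing a GO branch:   {within:.3f}")
print(f"mean cosine, genes in different branches: {between:.3f}")

m = gofs_matrix(emb, circ_gene, ["circA", "circB", "circAB"])
print("\nGOFS matrix (best-match average over gene sets):")
print(m.to_frame().round(3))
# Within-branch gene pairs average higher than cross-branch pairs, and
# circAB, whose genes bridge both branches, sits between circA and circB.
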