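"""Disease semantic similarity on a tiny hand-built DAG.

Builds a five-node disease hierarchy, computes the decayed ancestor
contributions of one disease, the semantic similarity of two sibling
diseases, and the circRNA-level CDFS entry for two circRNAs annotated to
those siblings.
"""

from mscfs import AssociationTable, cdfs_matrix, disease_pair_similarity, semantic_profile
from mscfs.disease import DiseaseDAG

# root <- cancer <- {thyroid carcinoma, lung carcinoma}; diabetes separate
dag = DiseaseDAG(
    nodes=frozenset({"root", "cancer", "thyroid carcinoma",
                     "lung carcinoma", "diabetes"}),
    parents={
        "cancer": frozenset({"root"}),
        "thyroid carcinoma": frozenset({"cancer"}),
        "lung carcinoma": frozenset({"cancer"}),
        "diabetes": frozenset({"root"}),
        "root": frozenset(),
    },
    delta=0.5,
)

profile = semantic_profile(dag, "thyroid carcinoma")
print("ancestor contributions of 'thyroid carcinoma':")
for d, v in sorted(profile.contributions.items(), key=lambda kv: -kv[1]):
    print(f"  {d:20s} {v:.3f}")
print(f"semantic value DV = {profile.dv:.3f}")
# Each hop up the hierarchy halves the contribution (delta = 0.5); DV sums them.

s = disease_pair_similarity(dag, "thyroid carcinoma", "lung carcinoma")
print(f"\nS(thyroid carcinoma, lung carcinoma) = {s:.3f}")
# Siblings share 'cancer' and 'root', so about half their semantic mass overlaps.

assoc = AssociationTable.from_pairs("circ-disease", [
    ("circTP53", "thyroid carcinoma"),
    ("circKRAS", "lung carcinoma"),
    ("circMET", "diabetes"),
])
m = cdfs_matrix(dag, assoc, ["circTP53", "circKRAS", "circMET"])
print("\nCDFS matrix (disease-based circRNA functional similarity):")
print(m.to_frame().round(3))
# circTP53 and circKRAS inherit the sibling-disease similarity; circMET,
# annotated to an unrelated disease, scores much lower against both.
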