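"""Synthetic datasets with planted functional clusters.

The generator emulates the shapes of the real inputs — a MeSH-style disease
tree, a GO-style term hierarchy with gene annotations, circBase-style
sequences, starBase-style miRNA links and an expression matrix — while
planting a known cluster structure: circRNAs in the same cluster are
annotated to diseases in the same branch of the disease tree, to genes
annotated in the same GO subtree, carry sequences mutated from a shared
cluster ancestor, bind overlapping miRNA pools, and have correlated
expression profiles.  ``noise`` is the per-element corruption probability
(and the per-base substitution rate for sequences); at noise=0 every
within-cluster signal is exact.  Everything is deterministic for a fixed
config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .disease import DiseaseDAG
from .fusion import FusionWeights
from .io import (
    AssociationTable,
    OntologyGraph,
    SequenceRecord,
    SimilarityMatrix,
    write_association_table,
    write_expression_table,
    write_fasta,
    write_obo,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "make_dataset", "make_planted_fusion", "write_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and noise parameters of the synthetic study system."""

    n_circ: int = 30
    n_disease: int = 40
    dag_depth: int = 4
    dag_branching: int = 2
    n_gene: int = 40
    n_go: int = 62
    go_depth: int = 4
    seq_len_range: tuple[int, int] = (200, 500)
    n_mirna: int = 40
    n_clusters: int = 3
    noise: float = 0.1
    seed: int = 0
    n_samples: int = 10           # expression samples per circRNA
    diseases_per_circ: int = 3
    annotations_per_gene: int = 4
    genes_per_circ: int = 3

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_disease", "n_gene", "n_go", "n_mirna",
                     "n_clusters", "dag_depth", "dag_branching", "go_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError(f"noise must lie in [0, 1], got {self.noise}")
        if self.n_clusters > self.n_circ:
            raise ValueError("n_clusters cannot exceed n_circ")
        lo, hi = self.seq_len_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid seq_len_range {self.seq_len_range}")


@dataclass
class SyntheticBundle:
    """All generated inputs plus the planted cluster labels."""

    config: SyntheticConfig
    dag: DiseaseDAG
    ontology: OntologyGraph
    circ_disease: AssociationTable
    circ_gene: AssociationTable
    gene_go: AssociationTable
    circ_mirna: AssociationTable
    sequences: list[SequenceRecord]
    expression: pd.DataFrame
    clusters: dict[str, int]

    @property
    def circ_ids(self) -> list[str]:
        return sorted(self.clusters)


def _tree(prefix: str, n_nodes: int, depth: int, branching: int):
    """Breadth-first rooted tree capped at n_nodes; returns (names, parent, depth)."""
    names = [f"{prefix}{i:04d}" for i in range(n_nodes)]
    parent: dict[str, str | None] = {names[0]: None}
    level = {names[0]: 0}
    frontier = [names[0]]
    nxt = 1
    while nxt < n_nodes and frontier:
        new_frontier = []
        for node in frontier:
            for _ in range(branching):
                if nxt >= n_nodes or level[node] + 1 > depth:
                    break
                child = names[nxt]
                parent[child] = node
                level[child] = level[node] + 1
                new_frontier.append(child)
                nxt += 1
        frontier = new_frontier
    used = [n for n in names if n in parent]
    return used, parent, level


def _subtree(nodes, parent, root):
    members = {root}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            if n not in members and parent[n] in members:
                members.add(n)
                changed = True
    return sorted(members)


def make_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a coherent dataset with ``n_clusters`` planted clusters."""
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters
    circ_ids = [f"circ-{i:04d}" for i in range(config.n_circ)]
    clusters = {c: i % k for i, c in enumerate(circ_ids)}

    # --- Disease DAG: rooted tree; each cluster anchored in its own branch.
    d_nodes, d_parent, d_level = _tree("MESH:D", config.n_disease,
                                       config.dag_depth, config.dag_branching)
    dag = DiseaseDAG(
        nodes=frozenset(d_nodes),
        parents={n: frozenset() if d_parent[n] is None else frozenset([d_parent[n]])
                 for n in d_nodes},
        delta=0.5,
    )
    d_root = d_nodes[0]
    branch_roots = sorted(n for n in d_nodes if d_parent[n] == d_root)
    cluster_disease_pool = []
    for ci in range(k):
        if branch_roots:
            sub = _subtree(d_nodes, d_parent, branch_roots[ci % len(branch_roots)])
        else:
            sub = [d_root]
        # core set: deepest nodes of the branch, deterministic
        core = sorted(sub, key=lambda n: (-d_level[n], n))[: config.diseases_per_circ]
        cluster_disease_pool.append(core)

    def corrupt(item: str, pool: list[str]) -> str:
        if config.noise > 0 and rng.random() < config.noise:
            return pool[int(rng.integers(len(pool)))]
        return item

    circ_disease = set()
    for c in circ_ids:
        for d in cluster_disease_pool[clusters[c]]:
            circ_disease.add((c, corrupt(d, d_nodes)))

    # --- GO tree + axioms (is_a in file order, a few part_of for flavour).
    g_nodes, g_parent, g_level = _tree("GO:", config.n_go, config.go_depth, 2)
    axioms: list[tuple[str, str, str]] = []
    for n in g_nodes:
        if g_parent[n] is not None:
            axioms.append((n, "is_a", g_parent[n]))
    for i, n in enumerate(g_nodes):
        if i % 7 == 3 and g_parent[n] is not None and g_parent[g_parent[n]] is not None:
            axioms.append((n, "part_of", g_parent[g_parent[n]]))
    ontology = OntologyGraph(terms=frozenset(g_nodes), axioms=axioms,
                             names={n: f"term {n}" for n in g_nodes})
    g_root = g_nodes[0]
    go_branch_roots = sorted(n for n in g_nodes if g_parent[n] == g_root)
    cluster_go_pool = []
    for ci in range(k):
        if go_branch_roots:
            sub = _subtree(g_nodes, g_parent, go_branch_roots[ci % len(go_branch_roots)])
        else:
            sub = [g_root]
        cluster_go_pool.append(sub)

    # --- Genes: contiguous blocks per cluster, annotated inside the cluster's
    # GO subtree.
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_gene)]
    gene_cluster = {g: i % k for i, g in enumerate(gene_ids)}
    gene_go = set()
    for g in gene_ids:
        pool = cluster_go_pool[gene_cluster[g]]
        n_ann = min(config.annotations_per_gene, len(pool))
        chosen = rng.choice(len(pool), size=n_ann, replace=False)
        for idx in chosen:
            gene_go.add((g, corrupt(pool[int(idx)], g_nodes)))

    circ_gene = set()
    for c in circ_ids:
        pool = [g for g in gene_ids if gene_cluster[g] == clusters[c]]
        n_g = min(config.genes_per_circ, len(pool))
        chosen = rng.choice(len(pool), size=n_g, replace=False)
        for idx in chosen:
            circ_gene.add((c, corrupt(pool[int(idx)], gene_ids)))

    # --- Sequences: per-cluster ancestor, i.i.d. point substitutions at the
    # noise rate (indels excluded).
    ancestors = []
    for ci in range(k):
        length = int(rng.integers(config.seq_len_range[0], config.seq_len_range[1] + 1))
        ancestors.append(rng.choice(4, size=length))
    sequences = []
    for c in circ_ids:
        anc = ancestors[clusters[c]].copy()
        if config.noise > 0:
            hit = rng.random(len(anc)) < config.noise
            shift = rng.integers(1, 4, size=int(hit.sum()))
            anc[hit] = (anc[hit] + shift) % 4
        sequences.append(SequenceRecord(c, "".join(_BASES[anc])))

    # --- miRNA pools: one block per cluster, shared by all members.
    mirna_ids = [f"miR-{i:04d}" for i in range(config.n_mirna)]
    circ_mirna = set()
    for c in circ_ids:
        pool = [m for i, m in enumerate(mirna_ids) if i % k == clusters[c]]
        for m in pool:
            circ_mirna.add((c, corrupt(m, mirna_ids)))

    # --- Expression: cluster mean + Gaussian noise with sd = noise.
    means = rng.normal(0.0, 1.0, size=(k, config.n_samples))
    prof = np.stack([
        means[clusters[c]] + (rng.normal(0.0, config.noise, config.n_samples)
                              if config.noise > 0 else 0.0)
        for c in circ_ids
    ])
    expression = pd.DataFrame(
        prof, index=circ_ids,
        columns=[f"sample{j:02d}" for j in range(config.n_samples)],
    )

    return SyntheticBundle(
        config=config,
        dag=dag,
        ontology=ontology,
        circ_disease=AssociationTable.from_pairs("circ-disease", circ_disease),
        circ_gene=AssociationTable.from_pairs("circ-gene", circ_gene),
        gene_go=AssociationTable.from_pairs("gene-go", gene_go),
        circ_mirna=AssociationTable.from_pairs("circ-mirna", circ_mirna),
        sequences=sequences,
        expression=expression,
        clusters=clusters,
    )


def write_dataset(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in its standard on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dag": outdir / "disease_dag.tsv",
        "circ_disease": outdir / "circ_disease.tsv",
        "circ_gene": outdir / "circ_gene.tsv",
        "gene_go": outdir / "gene_go.tsv",
        "ontology": outdir / "ontology.obo",
        "fasta": outdir / "sequences.fasta",
        "circ_mirna": outdir / "circ_mirna.tsv",
        "expression": outdir / "expression.tsv",
        "clusters": outdir / "clusters.tsv",
    }
    # roots re-enter the edge list as parents of their children
    with open(paths["dag"], "w") as fh:
        for child in sorted(bundle.dag.nodes):
            for parent in sorted(bundle.dag.parents.get(child, frozenset())):
                fh.write(f"{child}\t{parent}\n")
    write_association_table(bundle.circ_disease, paths["circ_disease"])
    write_association_table(bundle.circ_gene, paths["circ_gene"])
    write_association_table(bundle.gene_go, paths["gene_go"])
    write_association_table(bundle.circ_mirna, paths["circ_mirna"])
    write_obo(bundle.ontology, paths["ontology"])
    write_fasta(bundle.sequences, paths["fasta"])
    write_expression_table(bundle.expression, paths["expression"])
    with open(paths["clusters"], "w") as fh:
        for c in bundle.circ_ids:
            fh.write(f"{c}\t{bundle.clusters[c]}\n")
    return paths


def _random_similarity(rng: np.random.Generator, n: int, labels: list[str]) -> SimilarityMatrix:
    v = rng.uniform(0.0, 1.0, size=(n, n))
    v = np.triu(v, k=1)
    v = v + v.T
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(labels, v)


def make_planted_fusion(
    config: SyntheticConfig,
    weights: FusionWeights,
    sigma: float,
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Three random networks plus a CMS built as their noisy weighted sum.

    The returned (cdfs, gofs, sqfs, cms) are the harness for weight-recovery
    experiments: grid search on them should return ``weights`` whenever
    ``sigma`` is small.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(config.seed)
    n = config.n_circ
    labels = [f"circ-{i:04d}" for i in range(n)]
    cdfs = _random_similarity(rng, n, labels)
    gofs = _random_similarity(rng, n, labels)
    sqfs = _random_similarity(rng, n, labels)
    combo = (weights.alpha * cdfs.values + weights.beta * gofs.values
             + weights.gamma * sqfs.values)
    noise = rng.normal(0.0, sigma, size=(n, n)) if sigma > 0 else np.zeros((n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    cms_v = np.clip(combo + noise, 0.0, 1.0)
    np.fill_diagonal(cms_v, 1.0)
    cms = SimilarityMatrix(labels, cms_v)
    return cdfs, gofs, sqfs, cms
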