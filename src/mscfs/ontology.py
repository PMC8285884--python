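"""Ontology-corpus skip-gram embeddings and the GOFS similarity matrix.

The corpus renders each ontology axiom as one three-token sentence
(subject, relation keyword, object), each gene->GO annotation and each
circRNA->gene link as (entity, "has-function", target).  A skip-gram model
with negative sampling is trained on these sentences; gene-gene similarity
is the cosine of the learned vectors (clamped at 0), and circRNA-circRNA
similarity (GOFS) is the best-match average over the two circRNAs' gene
sets, mirroring the disease-based aggregation.

The trainer is a compact word2vec-style SGNS implementation: one input and
one output matrix, sigmoid updates on one positive and ``negative`` noise
tokens drawn from the unigram^0.75 distribution, learning rate decaying
linearly over the training schedule.  With a fixed seed and the fixed
sentence order it is reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import MISSING, AssociationTable, OntologyGraph, SimilarityMatrix

__all__ = [
    "Corpus",
    "Word2VecConfig",
    "EmbeddingTable",
    "build_corpus",
    "train_embeddings",
    "gene_similarity",
    "gofs_matrix",
]

HAS_FUNCTION = "has-function"


@dataclass(frozen=True)
class Corpus:
    """Token sentences over entity ids, relation keywords and term ids."""

    sentences: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for s in self.sentences:
            if len(s) < 3:
                raise ValueError(f"sentence {s} has fewer than 3 tokens")
            if any(not t for t in s):
                raise ValueError(f"sentence {s} contains an empty token")

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(t for s in self.sentences for t in s)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class Word2VecConfig:
    """Skip-gram training parameters (word2vec naming)."""

    sg: int = 1          # 1 = skip-gram; 0 = CBOW (not trained here)
    min_count: int = 1   # tokens rarer than this get no vector
    size: int = 200      # embedding dimension
    window: int = 10     # max distance between center and context token
    iter: int = 5        # training epochs
    negative: int = 4    # noise tokens per positive pair

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"size must be >= 2, got {self.size}")
        if self.sg not in (0, 1):
            raise ValueError("sg must be 0 or 1")


@dataclass
class EmbeddingTable:
    """Entity -> dense vector map plus the config and seed that produced it."""

    dim: int
    vectors: dict[str, np.ndarray]
    config: Word2VecConfig
    seed: int

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has wrong length")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# size={self.dim} seed={self.seed}\n")
            for tok in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[tok])
                fh.write(f"{tok}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, config: Word2VecConfig | None = None,
                 seed: int = 0) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        dim = len(next(iter(vectors.values())))
        cfg = config or Word2VecConfig(size=dim)
        return cls(dim=dim, vectors=vectors, config=cfg, seed=seed)


def build_corpus(
    ontology: OntologyGraph,
    gene_go: AssociationTable,
    circ_gene: AssociationTable,
) -> Corpus:
    """Render axioms and annotations as one-triple sentences.

    Order is deterministic: axioms in file order, then gene->GO annotation
    sentences sorted lexicographically, then circRNA->gene sentences sorted
    lexicographically.
    """
    if gene_go.kind != "gene-go":
        raise ValueError(f"expected gene-go table, got {gene_go.kind!r}")
    if circ_gene.kind != "circ-gene":
        raise ValueError(f"expected circ-gene table, got {circ_gene.kind!r}")

    sentences: list[tuple[str, ...]] = [
        (s, rel, o) for s, rel, o in ontology.axioms
    ]
    for gene, term in sorted(gene_go.pairs):
        if term not in ontology.terms:
            warnings.warn(
                f"annotation {gene} -> {term}: term not in ontology; kept",
                stacklevel=2,
            )
        sentences.append((gene, HAS_FUNCTION, term))
    for circ, gene in sorted(circ_gene.pairs):
        sentences.append((circ, HAS_FUNCTION, gene))
    return Corpus(tuple(sentences))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: Corpus,
    config: Word2VecConfig | None = None,
    seed: int = 0,
) -> EmbeddingTable:
    """Train skip-gram negative-sampling vectors on the corpus.

    Deterministic for a fixed (corpus, config, seed): sentences are visited
    in corpus order, negatives are drawn from a seeded generator, and the
    learning rate decays linearly from 0.025 to 0.0001 over all epochs.
    """
    config = config or Word2VecConfig()
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    if config.sg != 1:
        raise NotImplementedError("only skip-gram training (sg=1) is provided")

    counts: dict[str, int] = {}
    for sent in corpus.sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t in sorted(counts, key=lambda t: (-counts[t], t))
             if counts[t] >= config.min_count]
    if not vocab:
        raise ValueError("no token satisfies min_count")
    tok2id = {t: i for i, t in enumerate(vocab)}
    v, dim = len(vocab), config.size

    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(v, dim))
    w_out = np.zeros((v, dim))

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_p = freq / freq.sum()

    # Pre-encode sentences; tokens below min_count are dropped from training.
    encoded = [
        np.array([tok2id[t] for t in sent if t in tok2id], dtype=np.int64)
        for sent in corpus.sentences
    ]
    encoded = [s for s in encoded if len(s) >= 2]

    total = config.iter * len(encoded)
    alpha0, alpha_min = 0.025, 1e-4
    done = 0
    for _epoch in range(config.iter):
        for sent in encoded:
            alpha = max(alpha_min, alpha0 * (1 - done / total))
            done += 1
            n_tok = len(sent)
            for t in range(n_tok):
                center = sent[t]
                lo, hi = max(0, t - config.window), min(n_tok, t + config.window + 1)
                for c in range(lo, hi):
                    if c == t:
                        continue
                    context = sent[c]
                    negs = rng.choice(v, size=config.negative, p=noise_p)
                    targets = np.concatenate(([context], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    h = w_in[center]
                    scores = w_out[targets] @ h
                    g = (labels - _sigmoid(scores)) * alpha
                    grad_h = g @ w_out[targets]
                    w_out[targets] += np.outer(g, h)
                    w_in[center] = h + grad_h

    vectors = {t: w_in[i].copy() for t, i in tok2id.items()}
    return EmbeddingTable(dim=dim, vectors=vectors, config=config, seed=seed)


def gene_similarity(emb: EmbeddingTable, g1: str, g2: str) -> float:
    """Cosine similarity of two entity vectors, clamped to [0, 1]."""
    for g in (g1, g2):
        if g not in emb.vectors:
            raise KeyError(f"no vector for entity {g!r}")
    a, b = emb.vectors[g1], emb.vectors[g2]
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, 0.0, 1.0))


def gofs_matrix(
    emb: EmbeddingTable,
    circ_gene: AssociationTable,
    circ_ids: Sequence[str],
) -> SimilarityMatrix:
    """CircRNA similarity as best-match average over associated gene sets.

    Genes with no trained vector are dropped from the sets with a warning;
    circRNAs whose effective gene set is empty get NA off-diagonal entries.
    """
    if circ_gene.kind != "circ-gene":
        raise ValueError(f"expected circ-gene table, got {circ_gene.kind!r}")
    circ_ids = list(circ_ids)
    if not circ_ids:
        raise ValueError("circ_ids must be non-empty")

    gene_sets: dict[str, list[str]] = {}
    for c in circ_ids:
        genes = sorted(circ_gene.rights(c))
        kept = [g for g in genes if g in emb.vectors]
        dropped = set(genes) - set(kept)
        if dropped:
            warnings.warn(
                f"{c}: genes without vectors dropped: {sorted(dropped)}",
                stacklevel=2,
            )
        gene_sets[c] = kept

    all_genes = sorted({g for gs in gene_sets.values() for g in gs})
    pos = {g: i for i, g in enumerate(all_genes)}
    if all_genes:
        mat = np.stack([emb.vectors[g] for g in all_genes])
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        unit = mat / norms
        sim = np.clip(unit @ unit.T, 0.0, 1.0)
    else:
        sim = np.zeros((0, 0))

    n = len(circ_ids)
    values = np.full((n, n), MISSING)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        gi = gene_sets[circ_ids[i]]
        for j in range(i + 1, n):
            gj = gene_sets[circ_ids[j]]
            if not gi or not gj:
                continue
            idx_i = [pos[g] for g in gi]
            idx_j = [pos[g] for g in gj]
            block = sim[np.ix_(idx_i, idx_j)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(gi) + len(gj)
            )
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(circ_ids, values)
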