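"""Disease semantic similarity over a MeSH-style DAG, aggregated to CDFS.

The model is the Wang-style DAG measure: each disease D spans a sub-DAG of
its ancestors; an ancestor d contributes ``max(delta * contribution of the
best child of d on a path to D)``, so the contribution decays by the
semantic contribution factor delta per hop along the best (shortest) path.
Two diseases are similar in proportion to the contributions of their shared
ancestors relative to their total semantic values.  CircRNA-level similarity
(CDFS) is the best-match average of disease-set similarities across the two
circRNAs' annotated disease sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import MISSING, AssociationTable, SimilarityMatrix

__all__ = [
    "DiseaseDAG",
    "SemanticProfile",
    "semantic_profile",
    "disease_pair_similarity",
    "disease_set_similarity",
    "cdfs_matrix",
]


@dataclass(frozen=True)
class DiseaseDAG:
    """Disease nodes with child->parent edges and contribution factor delta."""

    nodes: frozenset[str]
    parents: dict[str, frozenset[str]]
    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie strictly in (0, 1), got {self.delta}")
        for node, ps in self.parents.items():
            unknown = ps - self.nodes
            if unknown:
                raise ValueError(f"node {node!r} has undeclared parents {sorted(unknown)}")
        # children map derived once; acyclicity is the reader's concern but a
        # cheap check here guards programmatic construction too.
        children: dict[str, set[str]] = {n: set() for n in self.nodes}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        object.__setattr__(
            self, "_children", {n: frozenset(c) for n, c in children.items()}
        )
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(n: str, stack: list[str]) -> None:
            state[n] = 1
            for p in self.parents.get(n, frozenset()):
                if state.get(p) == 1:
                    raise ValueError(f"cycle through {p!r} in disease DAG")
                if p not in state:
                    visit(p, stack)
            state[n] = 2

        for n in self.nodes:
            if n not in state:
                visit(n, [])

    def children(self, node: str) -> frozenset[str]:
        return self._children.get(node, frozenset())  # type: ignore[attr-defined]

    def ancestors(self, node: str) -> frozenset[str]:
        """Ancestor closure of ``node``, including the node itself (T_a)."""
        if node not in self.nodes:
            raise KeyError(f"disease {node!r} not in DAG")
        closure = {node}
        frontier = [node]
        while frontier:
            n = frontier.pop()
            for p in self.parents.get(n, frozenset()):
                if p not in closure:
                    closure.add(p)
                    frontier.append(p)
        return frozenset(closure)


@dataclass(frozen=True)
class SemanticProfile:
    """Contribution of each ancestor of a disease, and their sum DV."""

    disease: str
    contributions: dict[str, float]
    dv: float = field(init=False)

    def __post_init__(self) -> None:
        if self.contributions.get(self.disease) != 1.0:
            raise ValueError("self-contribution must be exactly 1")
        object.__setattr__(self, "dv", float(sum(self.contributions.values())))


def semantic_profile(dag: DiseaseDAG, disease: str) -> SemanticProfile:
    """Decayed contribution of every ancestor of ``disease``.

    The query disease contributes 1; any other ancestor d contributes
    ``delta * max over children of d inside the closure``, i.e. delta raised
    to the shortest hop count from the query up to d.
    """
    closure = dag.ancestors(disease)  # raises KeyError if absent

    memo: dict[str, float] = {disease: 1.0}

    def contrib(d: str) -> float:
        if d in memo:
            return memo[d]
        kids = [c for c in dag.children(d) if c in closure]
        value = dag.delta * max(contrib(c) for c in kids)
        memo[d] = value
        return value

    contributions = {d: contrib(d) for d in closure}
    return SemanticProfile(disease=disease, contributions=contributions)


def disease_pair_similarity(dag: DiseaseDAG, m: str, n: str) -> float:
    """Semantic similarity of two diseases from their shared ancestors.

    S(M, N) = sum over shared ancestors d of (D_M(d) + D_N(d)),
    divided by DV(M) + DV(N).  Symmetric, in [0, 1], and 1 when M == N.
    """
    pm = semantic_profile(dag, m)
    pn = semantic_profile(dag, n)
    shared = set(pm.contributions) & set(pn.contributions)
    num = sum(pm.contributions[d] + pn.contributions[d] for d in shared)
    return num / (pm.dv + pn.dv)


def disease_set_similarity(
    dag: DiseaseDAG, d: str, disease_set: Iterable[str]
) -> float:
    """Best match of disease ``d`` against a group of diseases (max rule)."""
    ds = list(disease_set)
    if not ds:
        raise ValueError("disease set must be non-empty")
    return max(disease_pair_similarity(dag, d, u) for u in ds)


def cdfs_matrix(
    dag: DiseaseDAG,
    circ_disease: AssociationTable,
    circ_ids: Sequence[str],
) -> SimilarityMatrix:
    """CircRNA functional similarity from disease associations.

    Entry (i, j) is the best-match average of the two circRNAs' disease
    sets:  [sum_d in D(i) Sd(d, D(j)) + sum_d in D(j) Sd(d, D(i))]
    / (|D(i)| + |D(j)|).  The diagonal is 1; off-diagonal entries where
    either circRNA has no disease evidence are NA so downstream fusion can
    renormalize (absence of evidence is not dissimilarity).
    """
    if circ_disease.kind != "circ-disease":
        raise ValueError(f"expected a circ-disease table, got {circ_disease.kind!r}")
    circ_ids = list(circ_ids)
    if not circ_ids:
        raise ValueError("circ_ids must be non-empty")

    disease_sets = {c: sorted(circ_disease.rights(c)) for c in circ_ids}
    referenced = sorted({d for ds in disease_sets.values() for d in ds})
    absent = [d for d in referenced if d not in dag.nodes]
    if absent:
        raise KeyError(f"diseases not in DAG: {absent[:5]}")

    # Cache pairwise disease similarities over the referenced diseases.
    profiles = {d: semantic_profile(dag, d) for d in referenced}
    pos = {d: i for i, d in enumerate(referenced)}
    k = len(referenced)
    pair = np.ones((k, k))
    for a in range(k):
        pa = profiles[referenced[a]]
        for b in range(a + 1, k):
            pb = profiles[referenced[b]]
            shared = set(pa.contributions) & set(pb.contributions)
            num = sum(pa.contributions[d] + pb.contributions[d] for d in shared)
            pair[a, b] = pair[b, a] = num / (pa.dv + pb.dv)

    n = len(circ_ids)
    values = np.full((n, n), MISSING)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        di = disease_sets[circ_ids[i]]
        for j in range(i + 1, n):
            dj = disease_sets[circ_ids[j]]
            if not di or not dj:
                continue
            s_ij = sum(max(pair[pos[d], pos[u]] for u in dj) for d in di)
            s_ji = sum(max(pair[pos[d], pos[u]] for u in di) for d in dj)
            values[i, j] = values[j, i] = (s_ij + s_ji) / (len(di) + len(dj))
    return SimilarityMatrix(circ_ids, values)
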