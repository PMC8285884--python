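"""Readers and writers for every external file the pipeline touches.

All tabular formats are tab-separated UTF-8; lines starting with ``#`` are
comments.  Identifiers are normalized by trimming surrounding whitespace and
collapsing internal whitespace runs to a single space; case is preserved
(MeSH headings are case-significant).  Missing similarity values are
serialized as ``NA``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AssociationTable",
    "SimilarityMatrix",
    "OntologyGraph",
    "ASSOCIATION_KINDS",
    "MISSING",
    "read_fasta",
    "write_fasta",
    "read_association_table",
    "write_association_table",
    "read_disease_dag",
    "read_ontology",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_expression_table",
    "normalize_id",
]

#: Sentinel used for undefined similarity entries (serialized as "NA").
MISSING = float("nan")

ASSOCIATION_KINDS = frozenset({"circ-disease", "circ-gene", "circ-mirna", "gene-go"})

# IUPAC nucleotide one-letter codes, including U and N.
_IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

_WS_RUN = re.compile(r"\s+")


def normalize_id(raw: str) -> str:
    """Trim and collapse internal whitespace runs to one space."""
    return _WS_RUN.sub(" ", raw.strip())


@dataclass(frozen=True)
class SequenceRecord:
    """A circRNA sequence: identifier plus uppercase nucleotide string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass
class AssociationTable:
    """A bipartite mapping, e.g. circRNA -> diseases or gene -> GO terms.

    ``rights(left)`` returns the (possibly empty) set of right-hand partners
    of a left-hand entity; absent entities map to the empty set.
    """

    kind: str
    pairs: frozenset[tuple[str, str]]
    _index: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ASSOCIATION_KINDS:
            raise ValueError(
                f"unknown association kind {self.kind!r}; expected one of "
                f"{sorted(ASSOCIATION_KINDS)}"
            )
        index: dict[str, set[str]] = {}
        for left, right in self.pairs:
            if not left or not right:
                raise ValueError("association pair with empty identifier")
            index.setdefault(left, set()).add(right)
        object.__setattr__(
            self, "_index", {k: frozenset(v) for k, v in index.items()}
        )

    @classmethod
    def from_pairs(cls, kind: str, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        return cls(kind=kind, pairs=frozenset((l, r) for l, r in pairs))

    def rights(self, left: str) -> frozenset[str]:
        return self._index.get(left, frozenset())

    @property
    def lefts(self) -> frozenset[str]:
        return frozenset(self._index)

    @property
    def right_entities(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SimilarityMatrix:
    """A symmetric labeled similarity matrix with values in [0, 1] or NaN.

    NaN marks pairs for which the modality carries no evidence; the diagonal
    is exactly 1 for self-comparable entities.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in similarity matrix")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol, equal_nan=True):
            raise ValueError("similarity matrix is not symmetric")
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < -atol or finite.max() > 1 + atol):
            raise ValueError("similarity values outside [0, 1]")
        diag = np.diag(v)
        bad = ~(np.isnan(diag) | np.isclose(diag, 1.0, atol=atol))
        if bad.any():
            lbl = self.labels[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"diagonal entry for {lbl!r} is neither 1 nor NA")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def reorder(self, labels: list[str]) -> "SimilarityMatrix":
        """Return a copy restricted to / reordered by ``labels``."""
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels absent from matrix: {missing[:5]}")
        idx = np.array([pos[l] for l in labels])
        return SimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class OntologyGraph:
    """Ontology terms plus (subject, relation, object) axiom triples."""

    terms: frozenset[str]
    axioms: list[tuple[str, str, str]]
    names: Mapping[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercase, validated).

    T is preserved here; mapping T to U is the sequence-similarity layer's
    concern.  Raises on empty files, duplicate ids, and non-IUPAC symbols.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = normalize_id(rec.id)
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace(" ", "")
        for pos, ch in enumerate(seq):
            if ch not in _IUPAC_NT:
                raise ValueError(
                    f"sequence {rid!r}: invalid symbol {ch!r} at position {pos}"
                )
        records.append(SequenceRecord(rid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Association tables


def _iter_tsv_rows(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_association_table(
    path: str | Path, kind: str, header: bool = False
) -> AssociationTable:
    """Read a two-column TSV of (left id, right id) pairs, deduplicated."""
    if kind not in ASSOCIATION_KINDS:
        raise ValueError(f"unknown association kind {kind!r}")
    pairs: set[tuple[str, str]] = set()
    first = True
    for lineno, fields in _iter_tsv_rows(path):
        if first and header:
            first = False
            continue
        first = False
        cells = [normalize_id(f) for f in fields]
        cells = [c for c in cells if c]
        if len(cells) < 2:
            raise ValueError(
                f"{path}:{lineno}: expected at least 2 non-empty fields"
            )
        pairs.add((cells[0], cells[1]))
    return AssociationTable.from_pairs(kind, pairs)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for left, right in sorted(table.pairs):
            fh.write(f"{left}\t{right}\n")


# ---------------------------------------------------------------------------
# Disease DAG

def read_disease_dag(
    path: str | Path,
    delta: float = 0.5,
    fmt: str = "edges",
):
    """Read a disease DAG from an edge list or MeSH tree-number TSV.

    fmt="edges": rows are (child id, parent id).
    fmt="tree":  rows are (disease id, dotted tree number); an edge is
    created from each tree number to its longest proper dotted prefix that
    is itself present.  Tree numbers with no parent prefix become roots.
    """
    from .disease import DiseaseDAG  # local import to avoid a cycle

    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    if fmt == "edges":
        for lineno, fields in _iter_tsv_rows(path):
            cells = [normalize_id(f) for f in fields if normalize_id(f)]
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected child and parent id")
            child, parent = cells[0], cells[1]
            nodes.update((child, parent))
            edges.add((child, parent))
    elif fmt == "tree":
        tree_to_disease: dict[str, str] = {}
        entries: list[tuple[str, str]] = []
        for lineno, fields in _iter_tsv_rows(path):
            cells = [normalize_id(f) for f in fields if normalize_id(f)]
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected disease id and tree number")
            disease, tn = cells[0], cells[1]
            tree_to_disease[tn] = disease
            entries.append((disease, tn))
            nodes.add(disease)
        for disease, tn in entries:
            parts = tn.split(".")
            for k in range(len(parts) - 1, 0, -1):
                prefix = ".".join(parts[:k])
                if prefix in tree_to_disease:
                    parent = tree_to_disease[prefix]
                    if parent != disease:
                        edges.add((disease, parent))
                    break
    else:
        raise ValueError(f"unknown disease DAG format {fmt!r}")

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"disease graph contains a cycle: {cycle}")

    parents: dict[str, frozenset[str]] = {
        n: frozenset(p for c, p in edges if c == n) for n in nodes
    }
    return DiseaseDAG(nodes=frozenset(nodes), parents=parents, delta=delta)


# ---------------------------------------------------------------------------
# Ontology (OBO subset)


def read_ontology(path: str | Path) -> OntologyGraph:
    """Read an OBO file into terms + axiom triples.

    Each ``is_a`` and each ``relationship`` line yields one
    (subject, relation, object) triple, in file order.  Obsolete terms are
    dropped.  Axioms referencing undeclared terms are kept with a warning.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except KeyError as exc:
        raise ValueError(f"{path}: OBO stanza missing required key {exc}") from exc
    declared = {n for n, d in graph.nodes(data=True) if d}
    names = {
        n: d.get("name", "") for n, d in graph.nodes(data=True) if d
    }
    axioms: list[tuple[str, str, str]] = []
    for subj, obj, rel in graph.edges(keys=True):
        axioms.append((subj, rel, obj))
        if obj not in declared:
            warnings.warn(
                f"axiom ({subj}, {rel}, {obj}) references undeclared term {obj}",
                stacklevel=2,
            )
    return OntologyGraph(terms=frozenset(declared), axioms=axioms, names=names)


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Serialize an OntologyGraph as a minimal OBO file."""
    by_subject: dict[str, list[tuple[str, str]]] = {}
    for s, rel, o in ontology.axioms:
        by_subject.setdefault(s, []).append((rel, o))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {ontology.names.get(term, term)}\n")
            for rel, o in by_subject.get(term, []):
                if rel == "is_a":
                    fh.write(f"is_a: {o}\n")
                else:
                    fh.write(f"relationship: {rel} {o}\n")


# ---------------------------------------------------------------------------
# Similarity matrices and expression tables


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    matrix.validate()
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        comment="#",
        keep_default_na=False,
        na_values=["NA"],
    )
    row_labels = [str(l) for l in df.index]
    col_labels = [str(l) for l in df.columns]
    if row_labels != col_labels:
        raise ValueError(
            f"{path}: row labels differ from column labels "
            f"(first rows {row_labels[:3]} vs columns {col_labels[:3]})"
        )
    return SimilarityMatrix(row_labels, df.to_numpy(dtype=float))


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix: rows = circRNAs, columns = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression table needs >= 2 samples")
    df.index = [normalize_id(str(i)) for i in df.index]
    return df.astype(float)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="")
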