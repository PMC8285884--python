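import numpy as np
import pytest

from mscfs import SyntheticConfig, make_dataset
from mscfs.disease import DiseaseDAG


@pytest.fixture
def chain_dag():
    """R <- P <- D, delta = 0.5."""
    return DiseaseDAG(
        nodes=frozenset({"R", "P", "D"}),
        parents={"D": frozenset({"P"}), "P": frozenset({"R"}), "R": frozenset()},
        delta=0.5,
    )


@pytest.fixture
def sibling_dag():
    """M and N are both children of P, delta = 0.5."""
    return DiseaseDAG(
        nodes=frozenset({"M", "N", "P"}),
        parents={"M": frozenset({"P"}), "N": frozenset({"P"}), "P": frozenset()},
        delta=0.5,
    )


@pytest.fixture(scope="session")
def two_cluster_bundle():
    """Noise-free two-cluster synthetic dataset shared across tests."""
    return make_dataset(SyntheticConfig(n_clusters=2, noise=0.0, seed=7))


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.4,
               delta: float = 0.5) -> DiseaseDAG:
    """Random DAG: node i may have parents among nodes with larger index."""
    names = [f"d{i}" for i in range(n_nodes)]
    parents = {}
    for i, name in enumerate(names):
        cand = names[i + 1:]
        chosen = [c for c in cand if rng.random() < p_edge]
        parents[name] = frozenset(chosen)
    return DiseaseDAG(nodes=frozenset(names), parents=parents, delta=delta)


def brute_force_contributions(dag: DiseaseDAG, disease: str) -> dict[str, float]:
    """Oracle: enumerate every upward path and keep the best decayed score."""
    best = {disease: 1.0}
    stack = [(disease, 0)]
    while stack:
        node, hops = stack.pop()
        for parent in dag.parents.get(node, frozenset()):
            score = dag.delta ** (hops + 1)
            if score > best.get(parent, 0.0):
                best[parent] = score
            stack.append((parent, hops + 1))
    return best


def upper_pairs(matrix):
    iu = np.triu_indices(matrix.n, k=1)
    return matrix.values[iu]
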