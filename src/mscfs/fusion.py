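"""Network fusion, miRNA-based reference similarity, tuning and evaluation.

The fused functional similarity is FS = alpha*CDFS + beta*GOFS + gamma*SQFS
with alpha + beta + gamma = 1.  Because real disease evidence is sparse,
entries where a modality is NA are by default renormalized over the
available modalities so FS stays on [0, 1]; a strict mode propagates NA.
Weights are tuned by grid search against the circRNA-miRNA Jaccard
similarity (CMS), maximizing the Pearson correlation over circRNA pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, AssociationTable, SimilarityMatrix

__all__ = [
    "FusionWeights",
    "EvaluationResult",
    "fuse",
    "cms_matrix",
    "correlate",
    "grid_search",
    "expression_similarity_matrix",
    "binned_expression_correlation",
    "threshold_network",
]


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights on the CDFS, GOFS and SQFS networks."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name, w in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {w}")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.alpha + self.beta + self.gamma}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class EvaluationResult:
    """Pearson correlation between two similarity signals over circRNA pairs."""

    r: float
    p: float
    n_pairs: int
    per_bin: tuple[tuple[float, float, float, int], ...] | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


def _check_same_labels(mats: Sequence[SimilarityMatrix]) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            diff = next(
                (i, a, b) for i, (a, b) in enumerate(zip(ref, m.labels)) if a != b
            ) if len(ref) == len(m.labels) else (None, len(ref), len(m.labels))
            raise ValueError(f"similarity matrices have mismatched labels: {diff}")


def fuse(
    cdfs: SimilarityMatrix,
    gofs: SimilarityMatrix,
    sqfs: SimilarityMatrix,
    weights: FusionWeights,
    strict: bool = False,
) -> SimilarityMatrix:
    """Entry-wise weighted sum of the three networks.

    Where an input entry is NA the remaining weights are renormalized over
    the available modalities for that pair (default), or NA propagates
    (strict=True).  The diagonal is forced to 1.
    """
    _check_same_labels([cdfs, gofs, sqfs])
    stack = np.stack([cdfs.values, gofs.values, sqfs.values])
    w = np.array(weights.as_tuple())[:, None, None]
    present = ~np.isnan(stack)
    if strict:
        values = (stack * w).sum(axis=0)
    else:
        num = np.where(present, stack, 0.0) * w
        den = (present * w).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num.sum(axis=0) / den
        values[den == 0] = MISSING
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(list(cdfs.labels), values)


def cms_matrix(
    circ_mirna: AssociationTable, circ_ids: Sequence[str]
) -> SimilarityMatrix:
    """Jaccard similarity of the miRNA sets bound by each circRNA pair.

    Pairs where both miRNA sets are empty are NA (no evidence either way);
    the diagonal is 1.
    """
    if circ_mirna.kind != "circ-mirna":
        raise ValueError(f"expected circ-mirna table, got {circ_mirna.kind!r}")
    circ_ids = list(circ_ids)
    if not circ_ids:
        raise ValueError("circ_ids must be non-empty")
    sets = [circ_mirna.rights(c) for c in circ_ids]
    n = len(circ_ids)
    values = np.full((n, n), MISSING)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            if not union:
                continue
            values[i, j] = values[j, i] = len(sets[i] & sets[j]) / len(union)
    return SimilarityMatrix(circ_ids, values)


def _paired_upper_triangle(
    a: SimilarityMatrix, b: SimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    common = [l for l in a.labels if l in set(b.labels)]
    if len(common) < 2:
        raise ValueError("fewer than 2 shared labels between matrices")
    av = a.reorder(common).values
    bv = b.reorder(common).values
    iu = np.triu_indices(len(common), k=1)
    x, y = av[iu], bv[iu]
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def correlate(a: SimilarityMatrix, b: SimilarityMatrix) -> EvaluationResult:
    """Pearson correlation over strictly-upper-triangle pairs defined in both."""
    x, y = _paired_upper_triangle(a, b)
    if len(x) < 3:
        raise ValueError(f"only {len(x)} usable pairs; need at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance over the compared pairs")
    r, p = stats.pearsonr(x, y)
    return EvaluationResult(r=float(r), p=float(p), n_pairs=len(x))


def enumerate_weights(step: float = 0.1, alpha_max: float = 0.2) -> list[FusionWeights]:
    """All (alpha, beta, gamma) on the grid with the stated constraints."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 evenly")
    a_max = round(alpha_max / step)
    if abs(a_max * step - alpha_max) > 1e-9:
        raise ValueError(f"alpha_max {alpha_max} is not a multiple of step {step}")
    combos: list[FusionWeights] = []
    for ai in range(a_max + 1):
        for bi in range(m + 1):
            gi = m - ai - bi
            if gi < 0:
                continue
            combos.append(FusionWeights(ai * step, bi * step, gi * step))
    if not combos:
        raise ValueError("no valid weight combination on the grid")
    return combos


def grid_search(
    cdfs: SimilarityMatrix,
    gofs: SimilarityMatrix,
    sqfs: SimilarityMatrix,
    cms: SimilarityMatrix,
    step: float = 0.1,
    alpha_max: float = 0.2,
) -> tuple[FusionWeights, list[tuple[FusionWeights, EvaluationResult]]]:
    """Tune fusion weights against CMS by maximizing Pearson r.

    Returns the best weights (ties broken by smaller p, then lexicographic
    (alpha, beta)) and the full evaluation table.
    """
    table: list[tuple[FusionWeights, EvaluationResult]] = []
    for w in enumerate_weights(step=step, alpha_max=alpha_max):
        res = correlate(fuse(cdfs, gofs, sqfs, w), cms)
        table.append((w, res))
    best = min(table, key=lambda t: (-t[1].r, t[1].p, t[0].alpha, t[0].beta))
    return best[0], table


def expression_similarity_matrix(expr: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise absolute Pearson correlation of expression profiles."""
    if expr.shape[1] < 2:
        raise ValueError("expression table needs >= 2 samples per circRNA")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.abs(np.corrcoef(expr.to_numpy(dtype=float)))
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix([str(i) for i in expr.index], values)


def binned_expression_correlation(
    fs: SimilarityMatrix,
    expr: pd.DataFrame,
    step: float = 0.1,
) -> EvaluationResult:
    """Correlation of functional and co-expression similarity after binning.

    Pairs are bucketed by functional similarity into bins
    [k*step, (k+1)*step); per-bin means of functional and expression
    similarity are computed and the Pearson correlation is taken over the
    bin means.  Empty bins are dropped; fewer than 2 occupied bins is an
    error.
    """
    expr_sim = expression_similarity_matrix(expr)
    x, y = _paired_upper_triangle(fs, expr_sim)
    if len(x) == 0:
        raise ValueError("no usable circRNA pairs")
    bins = np.floor(x / step).astype(int)
    per_bin: list[tuple[float, float, float, int]] = []
    for k in sorted(set(bins)):
        mask = bins == k
        per_bin.append(
            (k * step, float(x[mask].mean()), float(y[mask].mean()), int(mask.sum()))
        )
    if len(per_bin) < 2:
        raise ValueError(f"only {len(per_bin)} occupied bin(s); need at least 2")
    mean_fs = np.array([b[1] for b in per_bin])
    mean_ex = np.array([b[2] for b in per_bin])
    if mean_fs.std() == 0 or mean_ex.std() == 0:
        raise ValueError("zero variance across bin means")
    r, p = stats.pearsonr(mean_fs, mean_ex)
    return EvaluationResult(
        r=float(r), p=float(p), n_pairs=len(x), per_bin=tuple(per_bin)
    )


def threshold_network(
    fs: SimilarityMatrix, cutoff: float
) -> list[tuple[str, str, float]]:
    """Unordered circRNA pairs with similarity >= cutoff, sorted descending.

    The diagonal and NA entries are excluded; ties sort by labels.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    edges: list[tuple[str, str, float]] = []
    v = fs.values
    for i in range(fs.n):
        for j in range(i + 1, fs.n):
            score = v[i, j]
            if not np.isnan(score) and score >= cutoff:
                edges.append((fs.labels[i], fs.labels[j], float(score)))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return edges


def write_edge_list(edges: list[tuple[str, str, float]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("circ_a\tcirc_b\tscore\n")
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s!r}\n")
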