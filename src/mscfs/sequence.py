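"""Chaos-game representation of circRNA sequences and the SQFS matrix.

Each nucleotide maps the current point halfway toward its corner of the
unit square (A=(0,0), C=(1,0), G=(1,1), U=(0,1)), starting from the centre
(0.5, 0.5).  The trajectory is binned on a 2^s x 2^s grid; each cell
carries three attributes: the sum of x coordinates, the sum of y
coordinates, and the z-score of the cell's point count across all cells.
Concatenating the per-cell triples gives a feature vector of length
3 * 4^s (192 at the default s=3); sequence similarity is the absolute
Pearson correlation of two feature vectors (a cosine variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import MISSING, SequenceRecord, SimilarityMatrix

__all__ = [
    "CGRTrajectory",
    "FCGRFeature",
    "cgr_trajectory",
    "fcgr_features",
    "fcgr_vector",
    "sqfs_matrix",
]

# Vertex per base; T is mapped to U before lookup.
_VERTICES = {
    "A": np.array([0.0, 0.0]),
    "C": np.array([1.0, 0.0]),
    "G": np.array([1.0, 1.0]),
    "U": np.array([0.0, 1.0]),
}

START = np.array([0.5, 0.5])


@dataclass(frozen=True)
class CGRTrajectory:
    """Ordered CGR points in the open unit square; start point excluded."""

    points: np.ndarray  # shape (n, 2)
    skipped: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if pts.size and not ((pts > 0).all() and (pts < 1).all()):
            raise ValueError("CGR points must lie strictly inside the unit square")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FCGRFeature:
    """Per-cell coordinate sums, counts and count z-scores on a 2^s grid."""

    s: int
    x_sums: np.ndarray
    y_sums: np.ndarray
    counts: np.ndarray
    z_scores: np.ndarray

    @property
    def n_grid(self) -> int:
        return 4 ** self.s

    @property
    def vector(self) -> np.ndarray:
        """Concatenation (X_i, Y_i, Z_i) over cells; length 3 * 4^s."""
        return np.column_stack([self.x_sums, self.y_sums, self.z_scores]).ravel()


def cgr_trajectory(record: SequenceRecord) -> CGRTrajectory:
    """Map a sequence to its chaos-game trajectory.

    T is read as U; symbols outside {A, C, G, U} are skipped without moving
    the point.  Raises if no usable nucleotide remains.
    """
    pos = START.copy()
    points: list[np.ndarray] = []
    skipped = 0
    for ch in record.sequence.upper():
        base = "U" if ch == "T" else ch
        vertex = _VERTICES.get(base)
        if vertex is None:
            skipped += 1
            continue
        pos = 0.5 * (pos + vertex)
        points.append(pos.copy())
    if not points:
        raise ValueError(f"sequence {record.id!r} has no usable nucleotides")
    return CGRTrajectory(points=np.array(points), skipped=skipped)


def fcgr_features(traj: CGRTrajectory, s: int = 3) -> FCGRFeature:
    """Bin a trajectory into the 2^s x 2^s frequency grid.

    Cells are half-open boxes [k/2^s, (k+1)/2^s) with the top/right border
    clamped inward, ordered row-major by (y cell, x cell).  The z-scores use
    the population standard deviation of the cell counts; a zero-variance
    count pattern yields all-zero z-scores.
    """
    if s < 1:
        raise ValueError(f"subdivision exponent must be >= 1, got {s}")
    if len(traj) == 0:
        raise ValueError("cannot bin an empty trajectory")
    side = 2 ** s
    n_grid = side * side
    cells_xy = np.minimum((traj.points * side).astype(int), side - 1)
    idx = cells_xy[:, 1] * side + cells_xy[:, 0]

    x_sums = np.bincount(idx, weights=traj.points[:, 0], minlength=n_grid)
    y_sums = np.bincount(idx, weights=traj.points[:, 1], minlength=n_grid)
    counts = np.bincount(idx, minlength=n_grid).astype(float)
    std = counts.std()  # population std
    if std > 0:
        z = (counts - counts.mean()) / std
    else:
        z = np.zeros(n_grid)
    return FCGRFeature(s=s, x_sums=x_sums, y_sums=y_sums, counts=counts, z_scores=z)


def fcgr_vector(record: SequenceRecord, s: int = 3) -> np.ndarray:
    return fcgr_features(cgr_trajectory(record), s=s).vector


def sqfs_matrix(
    records: Sequence[SequenceRecord],
    s: int = 3,
    metric: str = "pearson",
) -> SimilarityMatrix:
    """Sequence functional similarity of circRNAs from FCGR feature vectors.

    metric="pearson" (default): absolute Pearson correlation of the two
    feature vectors.  metric="cosine": dot product over norms, clamped at 0.
    Zero-variance feature vectors under Pearson give NA entries with a
    warning; the diagonal is always exactly 1.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequence records")
    if metric not in ("pearson", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record ids")
    feats = np.stack([fcgr_vector(r, s=s) for r in records])
    n = len(records)

    if metric == "pearson":
        stds = feats.std(axis=1)
        degenerate = stds == 0
        if degenerate.any():
            bad = [labels[i] for i in np.flatnonzero(degenerate)]
            warnings.warn(
                f"zero-variance feature vectors (entries set to NA): {bad}",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.abs(np.corrcoef(feats))
        values[degenerate, :] = MISSING
        values[:, degenerate] = MISSING
        values = np.clip(values, 0.0, 1.0)
    else:
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        unit = feats / norms
        values = np.clip(unit @ unit.T, 0.0, 1.0)

    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(labels, values)
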