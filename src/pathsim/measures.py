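"""Pairwise trajectory distances and the similarity matrix.

Four measures of increasing sophistication:

* mean Euclidean distance — per-frame feature-space distance averaged over
  time; requires equal-length, aligned trajectories;
* dependent DTW — dynamic time warping with the squared per-frame Euclidean
  distance as local cost, allowing nonlinear time alignment and unequal
  lengths; the reported value is the square root of the minimal cumulative
  squared cost, keeping units of nm;
* Procrustes disparity — residual sum of squares after optimal translation,
  scaling and orthogonal mapping of one (centered, unit-norm) matrix onto
  the other; shape-only comparison, by default on every 5th frame;
* summed 1D Wasserstein — per-contact order-1 Wasserstein distance between
  the empirical value distributions, summed over contacts; ignores time
  order entirely.

Distances convert to similarities on [0, 1] via s_ij = 1 - d_ij / d_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from numba import njit
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance as _scipy_w1

from .features import ContactTrajectory, TrajectoryEnsemble

__all__ = [
    "DistanceMatrix",
    "SimilarityMatrix",
    "mean_euclidean",
    "dtw_dependent",
    "procrustes_distance",
    "wasserstein_distance",
    "distance_matrix",
    "to_similarity",
    "MEASURES",
]

Measure = Literal["euclidean", "dtw", "procrustes", "wasserstein"]


@dataclass
class DistanceMatrix:
    """Symmetric N x N pairwise distances with provenance."""

    values: np.ndarray
    measure: str
    preprocessing: str = "raw"
    traj_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v
        if not self.traj_ids:
            self.traj_ids = [str(i) for i in range(v.shape[0])]


@dataclass
class SimilarityMatrix:
    """N x N similarities on [0, 1], unit diagonal, with provenance."""

    values: np.ndarray
    measure: str
    preprocessing: str = "raw"
    traj_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        if not self.traj_ids:
            self.traj_ids = [str(i) for i in range(v.shape[0])]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (each pair once)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Pairwise measures
# ---------------------------------------------------------------------------

def mean_euclidean(a: ContactTrajectory, b: ContactTrajectory) -> float:
    """Per-frame Euclidean distance across contacts, averaged over frames."""
    if a.n_contacts != b.n_contacts:
        raise ValueError("trajectories have different contact sets")
    if a.n_frames != b.n_frames:
        raise ValueError("Euclidean distance requires equal-length, aligned trajectories")
    return float(np.linalg.norm(a.values - b.values, axis=1).mean())


@njit(cache=False)
def _dtw_dp(cost: np.ndarray) -> float:
    """Cumulative-cost dynamic program with steps (1,1), (1,0), (0,1)."""
    k, kp = cost.shape
    d = np.empty((k, kp))
    d[0, 0] = cost[0, 0]
    for j in range(1, kp):
        d[0, j] = cost[0, j] + d[0, j - 1]
    for i in range(1, k):
        d[i, 0] = cost[i, 0] + d[i - 1, 0]
        for j in range(1, kp):
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = cost[i, j] + best
    return d[k - 1, kp - 1]


def dtw_dependent(a: ContactTrajectory, b: ContactTrajectory,
                  squared: bool = False) -> float:
    """Dependent (multivariate) DTW distance.

    The local cost at grid cell (t, t') is the squared Euclidean distance
    between frame vectors; the warping path runs from (1, 1) to (K, K')
    under the usual monotonicity/adjacency constraints.  Returns the square
    root of the minimal cumulative cost unless ``squared`` is set.
    """
    if a.n_contacts != b.n_contacts:
        raise ValueError("trajectories have different contact sets")
    cost = cdist(a.values, b.values, metric="sqeuclidean")
    total = _dtw_dp(cost)
    return float(total) if squared else float(np.sqrt(total))


def procrustes_distance(a: ContactTrajectory, b: ContactTrajectory,
                        stride: int = 5) -> float:
    """Procrustes disparity between strided, standardized contact matrices.

    Both matrices are column-centered and scaled to unit Frobenius norm;
    the optimal orthogonal map (reflections allowed) comes from an SVD, and
    the disparity is the residual sum of squares, in [0, 2].  ``stride``
    downsamples the frames (default: every 5th) because the cost of the
    underlying SVD grows steeply with K while the resulting similarities
    barely change.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if a.n_contacts != b.n_contacts:
        raise ValueError("trajectories have different contact sets")
    va, vb = a.values[::stride], b.values[::stride]
    if va.shape[0] != vb.shape[0]:
        raise ValueError("Procrustes requires equal frame counts after striding")
    if va.shape[0] < 2:
        raise ValueError("need at least 2 frames after striding")
    for name, v in (("first", va), ("second", vb)):
        if np.linalg.norm(v - v.mean(axis=0)) == 0:
            raise ValueError(f"degenerate (constant) trajectory: {name} argument")
    _, _, disparity = _scipy_procrustes(va, vb)
    return float(disparity)


def wasserstein_distance(a: ContactTrajectory, b: ContactTrajectory) -> float:
    """Order-1 Wasserstein distance per contact column, summed over contacts.

    Each column is treated as an empirical distribution with uniform weights
    1/K; lengths may differ and time order is irrelevant.
    """
    if a.n_contacts != b.n_contacts:
        raise ValueError("trajectories have different contact sets")
    if a.n_frames == 0 or b.n_frames == 0:
        raise ValueError("empty columns")
    return float(sum(_scipy_w1(a.values[:, m], b.values[:, m])
                     for m in range(a.n_contacts)))


_PAIRWISE: dict[str, Callable[..., float]] = {
    "euclidean": mean_euclidean,
    "dtw": dtw_dependent,
    "procrustes": procrustes_distance,
    "wasserstein": wasserstein_distance,
}
MEASURES = tuple(_PAIRWISE)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def distance_matrix(ensemble: TrajectoryEnsemble, measure: Measure,
                    preprocessing: str = "raw", **measure_kwargs) -> DistanceMatrix:
    """All-pairs distance matrix for one measure.

    Pair evaluations are pure and order-independent; any failing pair
    raises with the offending trajectory ids.
    """
    if measure not in _PAIRWISE:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    fn = _PAIRWISE[measure]
    n = len(ensemble)
    ids = ensemble.traj_ids
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = fn(ensemble[i], ensemble[j], **measure_kwargs)
            except ValueError as exc:
                raise ValueError(
                    f"{measure} failed for pair ({ids[i]}, {ids[j]}): {exc}") from exc
    return DistanceMatrix(d, measure=measure, preprocessing=preprocessing, traj_ids=ids)


def to_similarity(dm: DistanceMatrix) -> SimilarityMatrix:
    """Affine map s_ij = 1 - d_ij / d_max onto [0, 1].

    The diagonal maps to 1 and the maximum-distance pair to exactly 0; rank
    order of pairs is reversed exactly (more distant = less similar).
    """
    dmax = dm.values.max()
    if dmax <= 0:
        raise ValueError("no contrast between trajectories (all distances zero)")
    return SimilarityMatrix(1.0 - dm.values / dmax, measure=dm.measure,
                            preprocessing=dm.preprocessing, traj_ids=list(dm.traj_ids))
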