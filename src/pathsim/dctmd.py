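"""Pathway-resolved free energies from nonequilibrium pulling work (dcTMD).

In constant-velocity constraint pulling, the work along the pulling
coordinate x is W(x) = int_{x0}^{x} f_c(x') dx'.  Averaging over N
independent realizations started from equilibrium, the second-order
cumulant expansion of the Jarzynski equality gives

    dG(x) ~= <W(x)> - (1 / 2 k_B T) <dW(x)^2>,

exact when W(x) is Gaussian-distributed.  The subtracted term is the
dissipative work W_diss(x).  Mixing trajectories that follow distinct
unbinding routes (and hence experience different friction) breaks the
Gaussian assumption and inflates W_diss, which is the core reason the
clustering stages of this package exist: the estimator is applied per
pathway cluster, each assumed to host a single route with Gaussian work.

Temperature is a required input everywhere; k_B = 0.008314462618 kJ/mol/K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm, shapiro

from .cluster import QUESTION_CLUSTER, Partition

__all__ = [
    "KB",
    "WorkEnsemble",
    "FreeEnergyProfile",
    "integrate_work",
    "free_energy",
    "pathwise_free_energy",
    "work_normality_diagnostics",
    "resample_works",
]

KB = 0.008314462618153241  # Boltzmann constant, kJ/mol/K

logger = logging.getLogger(__name__)


@dataclass
class WorkEnsemble:
    """Per-trajectory work curves on a common pulling-coordinate grid.

    ``x`` is the strictly increasing pulling coordinate (nm) shared by all
    members; ``works`` is (N, G) in kJ/mol with W(x0) = 0 for every member;
    ``temperature`` in K.
    """

    x: np.ndarray
    works: np.ndarray
    temperature: float
    traj_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.works = np.atleast_2d(np.asarray(self.works, dtype=float))
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("pulling-coordinate grid must be strictly increasing")
        if self.works.shape[1] != self.x.size:
            raise ValueError("work curves must live on the common x grid")
        if not np.all(np.isfinite(self.works)):
            raise ValueError("non-finite work values")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not np.allclose(self.works[:, 0], 0.0, atol=1e-9):
            raise ValueError("work curves must start at W(x0) = 0")
        if not self.traj_ids:
            self.traj_ids = [str(i) for i in range(self.works.shape[0])]

    @property
    def n(self) -> int:
        return self.works.shape[0]

    @property
    def kbt(self) -> float:
        return KB * self.temperature


@dataclass
class FreeEnergyProfile:
    """dcTMD estimate on a grid: dG = <W> - W_diss at every point."""

    x: np.ndarray
    deltaG: np.ndarray
    mean_work: np.ndarray
    dissipative_work: np.ndarray
    n_used: int

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.x, self.deltaG, self.mean_work,
                                self.dissipative_work])


def integrate_work(forces: np.ndarray, x: np.ndarray, temperature: float,
                   traj_ids: list[str] | None = None) -> WorkEnsemble:
    """Cumulative trapezoidal integration of constraint forces.

    ``forces`` is (N, G) in kJ/mol/nm on the strictly increasing grid ``x``
    (nm); the result satisfies W(x0) = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    if np.any(np.diff(x) <= 0):
        raise ValueError("pulling-coordinate grid must be strictly increasing")
    works = cumulative_trapezoid(forces, x, axis=1, initial=0.0)
    return WorkEnsemble(x, works, temperature, traj_ids=traj_ids or [])


def free_energy(works: WorkEnsemble, unbiased: bool = True) -> FreeEnergyProfile:
    """Second-order cumulant estimate dG(x) = <W(x)> - var W(x) / (2 k_B T).

    The variance uses the unbiased N-1 divisor by default (sensible for the
    small per-cluster N this is applied to); set ``unbiased=False`` for the
    plain N divisor.
    """
    if works.n < 2:
        raise ValueError("free-energy estimation needs at least 2 work curves")
    mean = works.works.mean(axis=0)
    var = works.works.var(axis=0, ddof=1 if unbiased else 0)
    wdiss = var / (2.0 * works.kbt)
    return FreeEnergyProfile(x=works.x.copy(), deltaG=mean - wdiss,
                             mean_work=mean, dissipative_work=wdiss,
                             n_used=works.n)


def pathwise_free_energy(works: WorkEnsemble, partition: Partition,
                         min_cluster_size: int = 100,
                         unbiased: bool = True) -> dict[int, FreeEnergyProfile]:
    """dcTMD per pathway cluster, for clusters of at least ``min_cluster_size``.

    The work distribution is only trustworthy Gaussian within a single
    pathway sampled well enough; the conventional floor is 100 trajectories
    (configurable downwards for small synthetic studies).  Too-small
    clusters and the '?' pseudo-cluster are skipped with a log message.
    """
    if partition.n != works.n:
        raise ValueError("partition and work ensemble cover different trajectories")
    profiles: dict[int, FreeEnergyProfile] = {}
    for cid in partition.cluster_ids():
        idx = partition.members(cid)
        if idx.size < min_cluster_size:
            logger.info("cluster %d skipped: %d < min_cluster_size=%d",
                        cid, idx.size, min_cluster_size)
            continue
        sub = WorkEnsemble(works.x, works.works[idx], works.temperature,
                           traj_ids=[works.traj_ids[i] for i in idx])
        profiles[cid] = free_energy(sub, unbiased=unbiased)
    if QUESTION_CLUSTER in partition.sizes():
        logger.info("'?' pseudo-cluster skipped (%d trajectories)",
                    partition.sizes()[QUESTION_CLUSTER])
    if not profiles:
        logger.warning("no cluster meets min_cluster_size=%d; empty result",
                       min_cluster_size)
    return profiles


def work_normality_diagnostics(works: WorkEnsemble,
                               x_probe: Sequence[float]) -> list[dict]:
    """Gaussianity diagnostics of the work distribution at probe points.

    For each probe coordinate (snapped to the nearest grid point) returns a
    record with the Shapiro-Wilk statistic and p-value plus paired
    (theoretical normal, sample) quantiles for a Q-Q plot.  Diagnostics
    only — nothing is rejected automatically.
    """
    if works.n < 8:
        raise ValueError("normality diagnostics need at least 8 work curves")
    records = []
    for xp in x_probe:
        g = int(np.argmin(np.abs(works.x - xp)))
        sample = np.sort(works.works[:, g])
        n = sample.size
        # Hazen plotting positions for the theoretical quantiles
        probs = (np.arange(1, n + 1) - 0.5) / n
        theo = norm.ppf(probs, loc=sample.mean(), scale=sample.std(ddof=1))
        stat, pvalue = shapiro(sample)
        records.append({
            "x": float(works.x[g]),
            "shapiro_statistic": float(stat),
            "pvalue": float(pvalue),
            "sample_quantiles": sample,
            "normal_quantiles": theo,
        })
    return records


def resample_works(x_new: np.ndarray, works: WorkEnsemble) -> WorkEnsemble:
    """Explicit linear resampling helper onto a new common grid.

    Work curves must share a grid for the cumulant estimator; this package
    never interpolates silently, so regridding is a deliberate call.
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new[0] < works.x[0] or x_new[-1] > works.x[-1]:
        raise ValueError("new grid extends beyond the data range")
    resampled = np.stack([np.interp(x_new, works.x, w) for w in works.works])
    resampled[:, 0] = 0.0 if np.isclose(x_new[0], works.x[0]) else resampled[:, 0]
    return WorkEnsemble(x_new, resampled - resampled[:, :1], works.temperature,
                        traj_ids=list(works.traj_ids))
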