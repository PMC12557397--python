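"""Preprocessing transforms for contact-distance ensembles.

Three optional stages, applied in a fixed order:

1. temporal Gaussian smoothing (per trajectory, per contact column),
2. normalization — either time-resolved (divide by the per-(t, m) ensemble
   mean) or global standardization (pooled zero mean / unit variance per
   contact),
3. contact PCA (projection onto leading eigenvectors of the pooled
   population covariance; default components 1-4).

The smoothing kernel is a normalized Gaussian of standard deviation
``sigma`` frames truncated at +/- ``sigma``; at the series edges the
truncated kernel is renormalized over the available frames, so constants are
preserved exactly and no data is fabricated beyond the ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .features import ContactTrajectory, TrajectoryEnsemble

__all__ = [
    "PreprocessConfig",
    "PCAModel",
    "gaussian_smooth",
    "time_normalize",
    "global_standardize",
    "fit_pca",
    "project_pca",
    "apply_preprocessing",
]

ZERO_MEAN_TOL = 1e-12  # nm; guard for the time-resolved division

Normalization = Literal["none", "time_resolved", "global"]


@dataclass
class PreprocessConfig:
    """Preprocessing chain configuration.

    ``smooth_sigma`` is the Gaussian filter standard deviation in frames
    (0 disables smoothing); ``normalization`` selects none / time-resolved /
    global; ``pca_components`` is an inclusive 1-based component range such
    as ``(1, 4)``, or None to skip PCA.  ``smooth_truncate`` widens the
    kernel truncation (in multiples of sigma) for comparison with common
    4-sigma-truncated filters; the default of 1 matches the summation
    window as defined.
    """

    smooth_sigma: int = 0
    normalization: Normalization = "none"
    pca_components: tuple[int, int] | None = None
    smooth_truncate: float = 1.0

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.normalization not in ("none", "time_resolved", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.pca_components is not None:
            lo, hi = self.pca_components
            if lo < 1 or hi < lo:
                raise ValueError("pca_components must be an inclusive range (lo, hi), lo >= 1")

    def fingerprint(self) -> str:
        """Short provenance tag recorded on distance/similarity matrices."""
        parts = []
        if self.smooth_sigma:
            parts.append(f"sigma={self.smooth_sigma}")
        if self.normalization == "time_resolved":
            parts.append("nt")
        elif self.normalization == "global":
            parts.append("n")
        if self.pca_components is not None:
            parts.append(f"PC{self.pca_components[0]};{self.pca_components[1]}")
        return "+".join(parts) if parts else "raw"


@dataclass
class PCAModel:
    """Eigendecomposition of the pooled contact covariance.

    ``eigenvectors`` has one eigenvector per row (row k = e_k), orthonormal;
    ``eigenvalues`` are sorted descending and sum to the total population
    variance of the fitted data; ``means`` are the pooled per-contact means.
    """

    eigenvectors: np.ndarray  # (M, M), rows e_k
    eigenvalues: np.ndarray   # (M,), descending
    means: np.ndarray         # (M,)

    def to_table(self) -> np.ndarray:
        """Eigenvalues and eigenvector components as one exportable array.

        Row k holds [lambda_k, e_k1 ... e_kM]; useful for reading off the
        relative contribution of individual contacts to each component.
        """
        return np.column_stack([self.eigenvalues, self.eigenvectors])


def _gaussian_kernel(sigma: int, truncate: float = 1.0) -> np.ndarray:
    half = max(int(round(truncate * sigma)), 1)
    nu = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (nu / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(traj: ContactTrajectory, sigma: int,
                    truncate: float = 1.0) -> ContactTrajectory:
    """Smooth each contact column with a truncated, renormalized Gaussian."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return traj
    w = _gaussian_kernel(sigma, truncate)
    # Dividing by the convolved window of ones renormalizes the kernel over
    # whatever frames are actually available near the edges.
    coverage = np.convolve(np.ones(traj.n_frames), w, mode="same")
    smoothed = np.empty_like(traj.values)
    for m in range(traj.n_contacts):
        smoothed[:, m] = np.convolve(traj.values[:, m], w, mode="same") / coverage
    return ContactTrajectory(smoothed, dt=traj.dt, traj_id=traj.traj_id,
                             contact_labels=list(traj.contact_labels))


def time_normalize(ensemble: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Divide each entry by the per-(t, m) mean over trajectories.

    Counteracts the growth of inter-trajectory spread from free diffusion in
    the unbound state.  Requires aligned trajectories (equal K).  After the
    transform the ensemble mean at every (t, m) is exactly 1.
    """
    if not ensemble.equal_length():
        raise ValueError("time-resolved normalization requires aligned trajectories")
    stack = ensemble.stacked()  # (N, K, M)
    mu = stack.mean(axis=0)     # (K, M)
    bad = np.argwhere(np.abs(mu) <= ZERO_MEAN_TOL)
    if bad.size:
        t, m = bad[0]
        raise ValueError(f"zero ensemble mean at time step {t}, contact {m}")
    return ensemble.with_values(list(stack / mu))


def global_standardize(ensemble: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Standardize each contact column pooled over trajectories and frames.

    Population convention: mean and variance use the divisor N*K (total
    pooled frame count), giving each column exactly zero mean and unit
    variance after the transform.
    """
    pooled = ensemble.pooled()
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)  # ddof=0, population
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance contact column(s): {dead.tolist()}")
    return ensemble.with_values([(t.values - mu) / sd for t in ensemble])


def fit_pca(ensemble: TrajectoryEnsemble) -> PCAModel:
    """Diagonalize the pooled population covariance of the contact columns."""
    pooled = ensemble.pooled()
    mu = pooled.mean(axis=0)
    x = pooled - mu
    cov = x.T @ x / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows e_k
    # Deterministic sign: largest-magnitude loading positive.
    for k in range(evecs.shape[0]):
        j = np.argmax(np.abs(evecs[k]))
        if evecs[k, j] < 0:
            evecs[k] = -evecs[k]
    return PCAModel(eigenvectors=evecs, eigenvalues=evals, means=mu)


def project_pca(ensemble: TrajectoryEnsemble, model: PCAModel,
                components: tuple[int, int] = (1, 4)) -> TrajectoryEnsemble:
    """Project onto principal components ``lo..hi`` (1-based, inclusive).

    PC_k(t) = e_k . (p(t) - mu).  The full-rank projection is unitary and
    preserves all pairwise frame distances.
    """
    m = ensemble.n_contacts
    lo, hi = components
    if lo < 1 or hi > m or hi < lo:
        raise ValueError(f"components {components} out of range [1, {m}]")
    sub = model.eigenvectors[lo - 1:hi]  # (k, M)
    new_labels = [f"PC{k}" for k in range(lo, hi + 1)]
    return ensemble.with_values(
        [(t.values - model.means) @ sub.T for t in ensemble],
        contact_labels=new_labels,
    )


def apply_preprocessing(ensemble: TrajectoryEnsemble, config: PreprocessConfig
                        ) -> tuple[TrajectoryEnsemble, PCAModel | None]:
    """Run the configured chain: smoothing -> normalization -> PCA."""
    out = ensemble
    if config.smooth_sigma:
        out = out.with_values(
            [gaussian_smooth(t, config.smooth_sigma, config.smooth_truncate).values
             for t in out])
    if config.normalization == "time_resolved":
        out = time_normalize(out)
    elif config.normalization == "global":
        out = global_standardize(out)
    model = None
    if config.pca_components is not None:
        model = fit_pca(out)
        out = project_pca(out, model, config.pca_components)
    return out, model
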