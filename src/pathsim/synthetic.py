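"""Ground-truth synthetic ensembles emulating biased pulling simulations.

The generator mimics the kinematics of the two biasing protocols:

* constraint (targeted-MD-like): the ligand's displacement along its pulling
  direction is exactly x0 + v*t — strictly linear in time;
* restraint (steered-MD-like): the displacement fluctuates around x0 + v*t
  as an Ornstein-Uhlenbeck process whose stationary variance is the
  equipartition value k_B*T / k_spring of a harmonic spring of stiffness
  ``spring_k``.

Perpendicular to the pulling direction the ligand performs a Gaussian
random walk whose END-POINT standard deviation is ``lateral_sigma`` (so the
bundle width is K-independent).  "Contacts" are pseudo-residue anchor
points placed in a spherical shell around the starting position, and the
feature matrix holds point-to-anchor distances plus i.i.d. Gaussian
measurement noise, floored at zero — the same K x M contact-distance shape
the real pipeline consumes.  Ground-truth labels record the pulling
direction of each trajectory.

A separate generator produces Gaussian work ensembles
W_i(x) = dG_true(x) + W_diss(x) + eta_i(x), with eta built from independent
Gaussian increments so its pointwise variance is exactly
2 k_B T W_diss(x) — the generative model under which the dcTMD cumulant
estimator is exact.

Everything is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dctmd import KB, WorkEnsemble
from .features import ContactTrajectory, TrajectoryEnsemble

__all__ = [
    "PathwayScenario",
    "generate_ensemble",
    "generate_overlapping_sets",
    "generate_work_ensemble",
    "PRESET_DIRECTIONS",
]

PRESET_DIRECTIONS: dict[str, list[tuple[float, float, float]]] = {
    # A: two well-separated directions; B: substantially overlapping pair;
    # C: all three merged (hardest).
    "A_like": [(1, 1, 0), (1, -1, 0)],
    "B_like": [(1, 0, 1), (1, -1, 0)],
    "C_like": [(1, 1, 0), (1, 0, 1), (1, -1, 0)],
}


@dataclass
class PathwayScenario:
    """Parameters of one synthetic pulling experiment.

    Defaults give 4 nm of ligand travel (v * dt * K): full unbinding, in
    which the ligand traverses and exits the 1-3 nm anchor shell, so
    contacts form, dip and break with pathway-specific temporal signatures.
    Bundle widths (lateral_sigma, noise_sigma) are small against the
    inter-pathway separation for well-separated direction sets.
    """

    directions: list[tuple[float, float, float]]
    n_per_direction: int = 40
    mode: str = "constraint"          # or "restraint"
    v: float = 0.02                   # pulling velocity, nm/ps
    dt: float = 1.0                   # frame spacing, ps
    K: int = 200                      # frames per trajectory
    x0: float = 0.0                   # initial offset along the direction, nm
    spring_k: float = 1000.0          # restraint spring, kJ/mol/nm^2
    temperature: float = 300.0        # K; sets the OU stationary variance
    ou_tau: float = 5.0               # OU correlation time, frames
    lateral_sigma: float = 0.1        # end-point std of the lateral walk, nm
    noise_sigma: float = 0.05         # contact-distance measurement noise, nm
    n_anchors: int = 20
    anchor_rmin: float = 1.0          # anchor shell inner radius, nm
    anchor_rmax: float = 3.0
    anchors: np.ndarray | None = None  # explicit (M, 3) layout overrides the shell
    anchor_seed: int | None = None    # None: deterministic quasi-uniform shell
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.directions) < 1:
            raise ValueError("need at least one pulling direction")
        if self.n_per_direction < 1:
            raise ValueError("n_per_direction must be >= 1")
        if self.mode not in ("constraint", "restraint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for val, name in ((self.v, "v"), (self.dt, "dt"), (self.spring_k, "spring_k"),
                          (self.temperature, "temperature"), (self.ou_tau, "ou_tau")):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lateral_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.K < 2:
            raise ValueError("K must be >= 2")

    def unit_directions(self) -> np.ndarray:
        d = np.asarray(self.directions, dtype=float)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def direction_labels(self) -> list[str]:
        return ["(" + ",".join(f"{c:g}" for c in d) + ")" for d in self.directions]


def _anchor_shell(scenario: PathwayScenario) -> np.ndarray:
    """Pseudo-residue anchors in the spherical shell around the start point.

    The default layout is deterministic and scenario-seed independent (see
    :func:`_channel_and_shell_anchors`); a seeded uniform-random shell is
    available via ``anchor_seed``, and an explicit ``anchors`` array wins
    over both.
    """
    if scenario.anchors is not None:
        a = np.asarray(scenario.anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("explicit anchors must be (M, 3)")
        return a
    n = scenario.n_anchors
    if scenario.anchor_seed is not None:
        rng = np.random.default_rng([scenario.anchor_seed, 0xA17C])
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r3 = rng.uniform(scenario.anchor_rmin ** 3, scenario.anchor_rmax ** 3, size=n)
        return u * np.cbrt(r3)[:, None]
    return _channel_and_shell_anchors(scenario)


_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


def _channel_and_shell_anchors(scenario: PathwayScenario) -> np.ndarray:
    """Deterministic layout: shell anchors plus channel-lining anchors.

    Half the anchors sit on a Fibonacci sphere with radii spread uniformly
    in volume across the shell, covering every direction quasi-uniformly so
    all pathways yield informative features.  The other half line each
    pulling direction's exit corridor — emulating the close-range channel
    residues that give a pathway its own contact signature — with a
    DIRECTION-SPECIFIC radial band and perpendicular offset.

    The banding matters: each contact column depends on its anchor only
    through the axial projection and miss distance seen from the path, so
    two pathways whose anchor environments sample the same (projection,
    miss) distribution produce orthogonally equivalent contact matrices
    that shape-based (Procrustes) comparison cannot tell apart.  Distinct
    per-direction bands — like the distinct residue arrangements of real
    exit channels — make the pathway prototypes genuinely incongruent.
    """
    units = scenario.unit_directions()
    n_dir = len(units)
    rmin, rmax = scenario.anchor_rmin, scenario.anchor_rmax
    n = scenario.n_anchors
    per_dir = (n // 2) // n_dir
    n_shell = n - per_dir * n_dir

    i = np.arange(n_shell, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / max(n_shell, 1)
    phi = _GOLDEN * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    r3 = rmin ** 3 + (i + 0.5) / max(n_shell, 1) * (rmax ** 3 - rmin ** 3)
    shell = dirs * np.cbrt(r3)[:, None]

    channel = []
    for d, u in enumerate(units):
        e1, e2 = _perp_basis(u)
        lo = rmin + (rmax - rmin) * d / n_dir
        hi = rmin + (rmax - rmin) * (d + 1) / n_dir
        offset = 0.25 + 0.15 * d
        for j in range(per_dir):
            r = lo + (j + 0.5) / max(per_dir, 1) * (hi - lo)
            ang = _GOLDEN * (j + d * per_dir)
            channel.append(r * u + offset * (np.cos(ang) * e1 + np.sin(ang) * e2))
    return np.vstack([shell] + [np.array(channel)]) if channel else shell


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _ou_path(rng: np.random.Generator, k: int, sigma_st: float, tau: float) -> np.ndarray:
    """Exact discrete-time Ornstein-Uhlenbeck path, stationary start."""
    phi = np.exp(-1.0 / tau)
    y = np.empty(k)
    y[0] = rng.normal(0.0, sigma_st)
    innov = rng.normal(0.0, sigma_st * np.sqrt(1.0 - phi * phi), size=k - 1)
    for t in range(1, k):
        y[t] = phi * y[t - 1] + innov[t - 1]
    return y


def generate_ensemble(scenario: PathwayScenario) -> TrajectoryEnsemble:
    """Simulate the scenario and return a labeled contact-distance ensemble."""
    n_total = scenario.n_per_direction * len(scenario.directions)
    if n_total < 2:
        raise ValueError("need at least 2 trajectories in total")
    rng = np.random.default_rng(scenario.seed)
    anchors = _anchor_shell(scenario)
    units = scenario.unit_directions()
    dir_labels = scenario.direction_labels()
    t_idx = np.arange(scenario.K, dtype=float)
    s_lin = scenario.x0 + scenario.v * scenario.dt * t_idx
    step_sigma = scenario.lateral_sigma / np.sqrt(max(scenario.K - 1, 1))
    sigma_st = np.sqrt(KB * scenario.temperature / scenario.spring_k)

    trajs: list[ContactTrajectory] = []
    labels: list[str] = []
    contact_labels = [f"anchor_{j}" for j in range(anchors.shape[0])]
    for d, (u, label) in enumerate(zip(units, dir_labels)):
        e1, e2 = _perp_basis(u)
        for i in range(scenario.n_per_direction):
            if scenario.mode == "constraint":
                s = s_lin
            else:
                s = s_lin + _ou_path(rng, scenario.K, sigma_st, scenario.ou_tau)
            lat1 = np.concatenate([[0.0], np.cumsum(rng.normal(0, step_sigma,
                                                               scenario.K - 1))])
            lat2 = np.concatenate([[0.0], np.cumsum(rng.normal(0, step_sigma,
                                                               scenario.K - 1))])
            start = rng.normal(0, scenario.lateral_sigma, size=2)
            pos = (s[:, None] * u
                   + (start[0] + lat1)[:, None] * e1
                   + (start[1] + lat2)[:, None] * e2)
            dist = np.linalg.norm(pos[:, None, :] - anchors[None, :, :], axis=2)
            if scenario.noise_sigma > 0:
                dist = dist + rng.normal(0, scenario.noise_sigma, size=dist.shape)
            values = np.clip(dist, 0.0, None)
            trajs.append(ContactTrajectory(values, dt=scenario.dt,
                                           traj_id=f"dir{d}_traj{i}",
                                           contact_labels=list(contact_labels)))
            labels.append(label)
    return TrajectoryEnsemble(trajs, labels=labels)


def generate_overlapping_sets(preset: str, seed: int = 0,
                              mode: str = "restraint",
                              **overrides) -> TrajectoryEnsemble:
    """Preset direction sets of graded difficulty.

    ``A_like``: two directions 90 degrees apart (easy, clearly bimodal
    similarities); ``B_like``: two directions 60 degrees apart whose bundles
    overlap substantially; ``C_like``: all three directions merged.
    """
    if preset not in PRESET_DIRECTIONS:
        raise ValueError(f"unknown preset {preset!r}; choose from {tuple(PRESET_DIRECTIONS)}")
    scenario = PathwayScenario(directions=list(PRESET_DIRECTIONS[preset]),
                               mode=mode, seed=seed, **overrides)
    return generate_ensemble(scenario)


def _on_grid(spec, x: np.ndarray) -> np.ndarray:
    arr = np.asarray(spec(x) if callable(spec) else spec, dtype=float)
    if arr.shape != x.shape:
        raise ValueError("spec must evaluate to one value per grid point")
    return arr


def generate_work_ensemble(deltaG_spec, wdiss_spec, temperature: float,
                           n: int, x_grid: Sequence[float],
                           seed: int = 0) -> WorkEnsemble:
    """Gaussian work curves realizing the dcTMD generative model.

    W_i(x) = dG_true(x) + W_diss(x) + eta_i(x), where eta_i accumulates
    independent Gaussian increments with variance 2 k_B T * dW_diss per grid
    step, so the pointwise work variance is exactly 2 k_B T W_diss(x).
    Requires dG_true(x0) = 0 and W_diss nonnegative, nondecreasing with
    W_diss(x0) = 0, so every curve starts at W(x0) = 0.
    """
    if n < 2:
        raise ValueError("need at least 2 work curves")
    x = np.asarray(x_grid, dtype=float)
    dg = _on_grid(deltaG_spec, x)
    wd = _on_grid(wdiss_spec, x)
    if wd[0] != 0 or dg[0] != 0:
        raise ValueError("dG_true and W_diss must vanish at x0 so that W(x0) = 0")
    dwd = np.diff(wd)
    if np.any(wd < 0) or np.any(dwd < -1e-12):
        raise ValueError("W_diss spec must be nonnegative and nondecreasing")
    rng = np.random.default_rng(seed)
    inc_sd = np.sqrt(2.0 * KB * temperature * np.clip(dwd, 0.0, None))
    eta = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rng.normal(0, 1, (n, x.size - 1)) * inc_sd, axis=1)],
        axis=1)
    return WorkEnsemble(x, dg + wd + eta, temperature)
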