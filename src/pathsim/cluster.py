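"""Leiden community detection under the Constant Potts Model (CPM).

The similarity matrix is treated as a complete weighted graph (nodes =
trajectories, edge weights = similarities s_ij); the Leiden algorithm
maximizes the CPM objective

    Phi_CPM = sum_c [ e_c - gamma * C(n_c, 2) ]

where e_c sums the similarities over unordered intra-cluster pairs and the
binomial term is the value a same-size cluster would reach if every pair had
similarity gamma.  The resolution gamma therefore acts as a soft
intra-cluster similarity bound, not a hard cutoff.  Candidate gamma values
come from quantiles of the pairwise-similarity distribution (median, third
quartile, their average).

Clusters with at most ``small_cluster_threshold`` (default 5) members can be
grouped into a single "?" pseudo-cluster for reporting; it carries the
reserved id -1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import igraph as ig
import leidenalg as la
import numpy as np

from .measures import SimilarityMatrix

__all__ = [
    "Partition",
    "QUESTION_CLUSTER",
    "select_gamma",
    "cpm_objective",
    "leiden_cpm",
    "group_small_clusters",
    "block_order",
    "write_partition",
    "read_partition",
]

QUESTION_CLUSTER = -1  # reserved id of the "?" pseudo-cluster

_GAMMA_RULES = {"Q2": 0.5, "Qmid": None, "Q3": 0.75}


@dataclass
class Partition:
    """A clustering of the N trajectories.

    ``assignment`` holds one cluster id per trajectory; proper clusters are
    numbered contiguously from 0 (by descending size, ties by first
    occurrence) and the "?" pseudo-cluster, if present, is id -1.
    ``objective`` is the achieved CPM value, recomputable from the
    assignment via :func:`cpm_objective`.
    """

    assignment: np.ndarray
    gamma: float
    seed: int = 0
    objective: float = 0.0
    small_cluster_threshold: int = 5
    grouped: bool = False
    traj_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n(self) -> int:
        return self.assignment.size

    def cluster_ids(self) -> np.ndarray:
        """Proper cluster ids present (excludes the '?' id)."""
        ids = np.unique(self.assignment)
        return ids[ids != QUESTION_CLUSTER]

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cid)


def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Contiguous ids from 0, descending cluster size, '?' (-1) untouched."""
    out = np.full_like(assignment, QUESTION_CLUSTER)
    ids, counts = np.unique(assignment[assignment != QUESTION_CLUSTER],
                            return_counts=True)
    first = [np.flatnonzero(assignment == c)[0] for c in ids]
    order = sorted(range(len(ids)), key=lambda k: (-counts[k], first[k]))
    for new, k in enumerate(order):
        out[assignment == ids[k]] = new
    return out


def select_gamma(s: SimilarityMatrix, rule: str = "Q2") -> float:
    """Resolution candidate from the pairwise-similarity distribution.

    Quantiles are taken over the off-diagonal upper-triangle entries only
    (self-similarities are not pairwise similarities), with linear
    interpolation between order statistics.  ``Qmid`` is (Q2 + Q3) / 2.
    """
    if rule not in _GAMMA_RULES:
        raise ValueError(f"unknown gamma rule {rule!r}; choose from {tuple(_GAMMA_RULES)}")
    vals = s.offdiag()
    if rule == "Qmid":
        return float((np.quantile(vals, 0.5) + np.quantile(vals, 0.75)) / 2)
    return float(np.quantile(vals, _GAMMA_RULES[rule]))


def cpm_objective(s: SimilarityMatrix, assignment: np.ndarray, gamma: float) -> float:
    """Evaluate Phi_CPM = sum_c [e_c - gamma * n_c(n_c-1)/2] for an assignment.

    Authoritative evaluator: used to rank Leiden restarts and to verify
    partitions against exhaustive enumeration in tests.  Singletons (and the
    '?' members, which form one ordinary cluster here) contribute via their
    pair count like any other cluster; a singleton contributes 0.
    """
    assignment = np.asarray(assignment)
    total = 0.0
    for cid in np.unique(assignment):
        idx = np.flatnonzero(assignment == cid)
        nc = idx.size
        if nc < 2:
            continue
        block = s.values[np.ix_(idx, idx)]
        e_c = (block.sum() - np.trace(block)) / 2.0
        total += e_c - gamma * nc * (nc - 1) / 2.0
    return float(total)


def leiden_cpm(s: SimilarityMatrix, gamma: float, seed: int = 0,
               restarts: int = 10, iterations: int = -1) -> Partition:
    """Maximize the CPM objective with Leiden on the complete weighted graph.

    Runs ``restarts`` independently seeded Leiden optimizations (seeds
    ``seed, seed+1, ...``) and keeps the partition with the highest CPM
    value as recomputed by :func:`cpm_objective`.  Deterministic for a fixed
    seed.  The achieved objective is always >= 0, the value of the
    all-singleton partition.
    """
    n = s.values.shape[0]
    iu = np.triu_indices(n, k=1)
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))
    weights = s.values[iu].tolist()
    graph = ig.Graph(n=n, edges=edges)
    best_assignment, best_obj = None, -np.inf
    for r in range(max(restarts, 1)):
        part = la.find_partition(
            graph, la.CPMVertexPartition, weights=weights,
            resolution_parameter=gamma, seed=int((seed + r) % (2 ** 31)),
            n_iterations=iterations,
        )
        assignment = np.array(part.membership)
        obj = cpm_objective(s, assignment, gamma)
        if obj > best_obj:
            best_obj, best_assignment = obj, assignment
    singleton_obj = 0.0
    if best_obj < singleton_obj:  # pragma: no cover - Leiden never returns worse
        best_assignment = np.arange(n)
        best_obj = singleton_obj
    return Partition(_relabel(best_assignment), gamma=float(gamma), seed=seed,
                     objective=best_obj, traj_ids=list(s.traj_ids))


def group_small_clusters(p: Partition, threshold: int | None = None) -> Partition:
    """Merge every cluster of size <= threshold into the '?' pseudo-cluster.

    Remaining proper clusters are renumbered contiguously from 0; threshold
    0 is the identity (no cluster has size <= 0).
    """
    thr = p.small_cluster_threshold if threshold is None else threshold
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    sizes = p.sizes()
    assignment = p.assignment.copy()
    for cid, size in sizes.items():
        if cid != QUESTION_CLUSTER and size <= thr:
            assignment[assignment == cid] = QUESTION_CLUSTER
    return replace(p, assignment=_relabel(assignment),
                   small_cluster_threshold=thr, grouped=True)


def block_order(s: SimilarityMatrix, p: Partition) -> np.ndarray:
    """Permutation placing same-cluster trajectories contiguously.

    Clusters are ordered by descending size (ties by cluster id), members
    keep their original relative order, and the '?' cluster goes last.
    Applying the permutation to S yields the block-ordered matrix used for
    inspection/plotting.
    """
    if p.n != s.values.shape[0]:
        raise ValueError("partition and similarity matrix size mismatch")
    sizes = p.sizes()
    proper = sorted((c for c in sizes if c != QUESTION_CLUSTER),
                    key=lambda c: (-sizes[c], c))
    order: list[int] = []
    for cid in proper:
        order.extend(p.members(cid).tolist())
    if QUESTION_CLUSTER in sizes:
        order.extend(p.members(QUESTION_CLUSTER).tolist())
    return np.array(order, dtype=int)


# ---------------------------------------------------------------------------
# Partition I/O (TSV with '#' metadata header)
# ---------------------------------------------------------------------------

def write_partition(p: Partition, path: str, gamma_rule: str = "") -> None:
    ids = p.traj_ids or [str(i) for i in range(p.n)]
    with open(path, "w") as f:
        f.write(f"# gamma_rule\t{gamma_rule}\n")
        f.write(f"# gamma\t{p.gamma!r}\n")
        f.write(f"# seed\t{p.seed}\n")
        f.write(f"# objective\t{p.objective!r}\n")
        f.write(f"# grouped\t{int(p.grouped)}\n")
        f.write(f"# small_cluster_threshold\t{p.small_cluster_threshold}\n")
        f.write("traj_id\tcluster_id\tgrouped_flag\n")
        for tid, cid in zip(ids, p.assignment):
            name = "?" if cid == QUESTION_CLUSTER else str(cid)
            f.write(f"{tid}\t{name}\t{int(cid == QUESTION_CLUSTER)}\n")


def read_partition(path: str) -> Partition:
    meta: dict[str, str] = {}
    ids: list[str] = []
    cids: list[int] = []
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value
            elif line.strip() and not line.startswith("traj_id"):
                tid, cid, _flag = line.rstrip("\n").split("\t")
                ids.append(tid)
                cids.append(QUESTION_CLUSTER if cid == "?" else int(cid))
    return Partition(np.array(cids), gamma=float(meta.get("gamma", "0") or 0),
                     seed=int(meta.get("seed", "0") or 0),
                     objective=float(meta.get("objective", "0") or 0),
                     small_cluster_threshold=int(meta.get("small_cluster_threshold", "5") or 5),
                     grouped=bool(int(meta.get("grouped", "0") or 0)),
                     traj_ids=ids)
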