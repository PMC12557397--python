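"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle deliberately avoids the implementation path it checks:
DTW by exhaustive warping-path enumeration, Procrustes by a direct
center/normalize/SVD/residual computation, Wasserstein by sorted samples or
explicit CDF integration, CPM by double-loop pair sums and exhaustive set
partitions, MI/NMI by a dict-based contingency table.
"""

import math

import numpy as np


def dtw_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum over ALL admissible warping paths of the summed squared costs.

    Iterative stack enumeration from cell (0, 0) to (K-1, K'-1) with steps
    (1,1), (1,0), (0,1).  Feasible for K, K' <= 8.
    """
    k, kp = len(a), len(b)
    cost = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    best = math.inf
    stack = [(0, 0, cost[0, 0])]
    while stack:
        i, j, acc = stack.pop()
        if acc >= best:
            continue
        if i == k - 1 and j == kp - 1:
            best = acc
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < k and nj < kp:
                stack.append((ni, nj, acc + cost[ni, nj]))
    return math.sqrt(best)


def procrustes_svd(a: np.ndarray, b: np.ndarray) -> float:
    """Disparity: center columns, scale to unit Frobenius norm, SVD residual."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    trace = np.linalg.svd(a.T @ b, compute_uv=False).sum()
    return 1.0 - trace ** 2


def wasserstein_sorted(u: np.ndarray, v: np.ndarray) -> float:
    """Equal-length closed form: mean absolute difference of sorted samples."""
    assert len(u) == len(v)
    return float(np.abs(np.sort(u) - np.sort(v)).mean())


def wasserstein_cdf(u: np.ndarray, v: np.ndarray) -> float:
    """General case: integrate |F_u - F_v| over the merged breakpoints."""
    xs = np.sort(np.concatenate([u, v]))
    fu = np.searchsorted(np.sort(u), xs, side="right") / len(u)
    fv = np.searchsorted(np.sort(v), xs, side="right") / len(v)
    return float(np.sum(np.abs(fu - fv)[:-1] * np.diff(xs)))


def cpm_double_loop(s: np.ndarray, assignment: np.ndarray, gamma: float) -> float:
    """Direct Phi_CPM: explicit double loop over unordered pairs."""
    total = 0.0
    n = len(assignment)
    for c in set(assignment.tolist()):
        members = [i for i in range(n) if assignment[i] == c]
        e_c = sum(s[i, j] for ii, i in enumerate(members) for j in members[ii + 1:])
        nc = len(members)
        total += e_c - gamma * nc * (nc - 1) / 2.0
    return total


def set_partitions(n: int):
    """All partitions of range(n) as assignment arrays (Bell(n) of them)."""
    def rec(i, parts):
        if i == n:
            yield [list(p) for p in parts]
            return
        for p in parts:
            p.append(i)
            yield from rec(i + 1, parts)
            p.pop()
        parts.append([i])
        yield from rec(i + 1, parts)
        parts.pop()

    for blocks in rec(0, []):
        assignment = np.empty(n, dtype=int)
        for cid, block in enumerate(blocks):
            assignment[block] = cid
        yield assignment


def cpm_exhaustive_max(s: np.ndarray, gamma: float) -> float:
    """Global CPM maximum over all set partitions (small n only)."""
    return max(cpm_double_loop(s, a, gamma) for a in set_partitions(s.shape[0]))


def mi_contingency(pred, truth) -> float:
    """MI in nats from an explicit dict-based contingency table."""
    n = len(pred)
    joint: dict = {}
    pk: dict = {}
    pc: dict = {}
    for a, b in zip(pred, truth):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pk[a] = pk.get(a, 0) + 1
        pc[b] = pc.get(b, 0) + 1
    mi = 0.0
    for (a, b), nij in joint.items():
        mi += (nij / n) * math.log(n * nij / (pk[a] * pc[b]))
    return mi


def entropy_direct(labels) -> float:
    n = len(labels)
    counts: dict = {}
    for a in labels:
        counts[a] = counts.get(a, 0) + 1
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def nmi_direct(pred, truth) -> float:
    hk, hc = entropy_direct(pred), entropy_direct(truth)
    if hk == 0.0 and hc == 0.0:
        return 1.0
    if hk == 0.0 or hc == 0.0:
        return 0.0
    return mi_contingency(pred, truth) / ((hk + hc) / 2.0)
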