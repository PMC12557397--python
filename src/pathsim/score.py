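"""Clustering evaluation via normalized mutual information.

Given a predicted clustering K (S clusters) and a ground-truth clustering C
(R clusters) of the same N elements, with P_K(i) = |K_i|/N etc.:

    H(K)  = -sum_i P_K(i) log P_K(i)
    MI    =  sum_ij |K_i n C_j|/N * log( N |K_i n C_j| / (|K_i| |C_j|) )
    NMI   =  MI / [(H(K) + H(C)) / 2]

Natural logarithms throughout (NMI itself is base-invariant; MI and H are
reported in nats).  Degenerate conventions: if both partitions are trivial
(single cluster each) NMI is 1; if exactly one is trivial NMI is 0.

The functions accept plain label sequences; labels may be any hashables and
both scores are invariant under relabeling.  Members of a grouped "?"
pseudo-cluster count as one ordinary cluster by default — pass
``exclude`` to drop them instead.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["entropy", "mutual_information", "nmi", "score_partitions"]


def _factorize(labels: Sequence) -> np.ndarray:
    """Indices of first occurrence per label; works for any mix of hashables."""
    index: dict = {}
    return np.array([index.setdefault(lab, len(index)) for lab in labels], dtype=int)


def _counts(labels: Sequence) -> np.ndarray:
    return np.bincount(_factorize(labels))


def entropy(labels: Sequence) -> float:
    """Shannon entropy (nats) of the cluster-size distribution."""
    counts = _counts(labels)
    if counts.sum() == 0:
        raise ValueError("empty partition")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(predicted: Sequence, truth: Sequence) -> float:
    """Mutual information (nats) between two clusterings of the same set."""
    if len(predicted) != len(truth):
        raise ValueError("partitions must cover the same elements")
    n = len(predicted)
    ki = _factorize(predicted)
    ci = _factorize(truth)
    table = np.zeros((ki.max() + 1, ci.max() + 1))
    np.add.at(table, (ki, ci), 1)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    mi = 0.0
    for i, j in zip(*np.nonzero(table)):
        nij = table[i, j]
        mi += (nij / n) * np.log(n * nij / (row[i] * col[j]))
    return float(max(mi, 0.0))


def nmi(predicted: Sequence, truth: Sequence) -> float:
    """Normalized mutual information in [0, 1], arithmetic-mean normalization."""
    hk = entropy(predicted)
    hc = entropy(truth)
    if hk == 0.0 and hc == 0.0:
        return 1.0
    if hk == 0.0 or hc == 0.0:
        return 0.0
    value = mutual_information(predicted, truth) / ((hk + hc) / 2.0)
    return float(min(value, 1.0))


def score_partitions(predicted: Sequence, truth: Sequence,
                     exclude: object | None = None) -> dict[str, float]:
    """NMI plus its ingredients, optionally excluding one predicted label.

    ``exclude`` drops elements whose PREDICTED label equals it (e.g. the
    "?" pseudo-cluster) from both partitions before scoring.
    """
    predicted = list(predicted)
    truth = list(truth)
    if exclude is not None:
        keep = [i for i, p in enumerate(predicted) if p != exclude]
        if not keep:
            raise ValueError("excluding that label removes every element")
        predicted = [predicted[i] for i in keep]
        truth = [truth[i] for i in keep]
    return {
        "nmi": nmi(predicted, truth),
        "mi": mutual_information(predicted, truth),
        "h_predicted": entropy(predicted),
        "h_truth": entropy(truth),
        "n": float(len(predicted)),
    }
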