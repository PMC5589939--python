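"""Single-layer analysis: modularity partitioning and the participation coefficient.

The partition is obtained by maximizing Newman-Girvan modularity with a
seeded, randomized greedy agglomeration (multilevel/Louvain, via igraph's C
implementation) run ``restarts`` times, keeping the best-Q result. The
participation coefficient of node *i* under a partition into modules m is

    PC_i = 1 - sum_m (k_{i,m} / k_i)^2

with PC_i = 0 for isolated nodes. On weighted inputs (e.g. the overlapping
flattened network) node strength replaces degree in both modularity and PC.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np

__all__ = ["Partition", "modularity_partition", "participation_coefficient"]


@dataclass(frozen=True)
class Partition:
    """Module label per node (contiguous 0..module_count-1) and its quality Q."""

    labels: np.ndarray
    module_count: int
    modularity: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.module_count)):
            raise ValueError("labels must be contiguous 0..module_count-1")

    def communities(self) -> list[set[int]]:
        return [set(np.flatnonzero(np.asarray(self.labels) == m)) for m in range(self.module_count)]


def _modularity_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity of a labeling on (possibly weighted) A."""
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A / two_m - np.outer(k, k) / two_m**2
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def modularity_partition(
    A: np.ndarray, seed: int = 0, restarts: int = 20, weighted: bool = False
) -> Partition:
    """Best-of-``restarts`` randomized greedy modularity maximization.

    Parameters
    ----------
    A : (n, n) array
        Symmetric adjacency (binary, or weighted with ``weighted=True``).
    seed : int
        Base seed; restart r runs under seed + r, so results are
        reproducible.
    restarts : int
        Number of independent randomized runs; the highest-modularity
        partition is returned.

    Raises
    ------
    ValueError
        If the graph has no edges (modularity is undefined).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not weighted:
        A = (A != 0).astype(float)
    n = A.shape[0]
    iu, ju = np.nonzero(np.triu(A, k=1))
    if len(iu) == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    g = ig.Graph(n=n, edges=list(zip(iu.tolist(), ju.tolist())))
    weights = A[iu, ju].tolist() if weighted else None

    best_q, best_labels = -np.inf, None
    state = _pyrandom.getstate()  # igraph draws from Python's global random
    try:
        for r in range(restarts):
            _pyrandom.seed(seed + r)
            clusters = g.community_multilevel(weights=weights)
            labels = np.array(clusters.membership)
            q = _modularity_q(A, labels)
            if q > best_q:
                best_q, best_labels = q, labels
    finally:
        _pyrandom.setstate(state)

    # relabel modules by smallest member for determinism
    order = sorted(set(best_labels.tolist()), key=lambda m: int(np.flatnonzero(best_labels == m)[0]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[m] for m in best_labels])
    return Partition(labels=labels, module_count=len(order), modularity=float(best_q))


def participation_coefficient(
    A: np.ndarray, part: Partition, weighted: bool = False
) -> tuple[np.ndarray, float]:
    """Per-node PC_i and the global PC (mean over all nodes).

    Isolated nodes (zero degree/strength) are assigned PC_i = 0.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    labels = np.asarray(part.labels)
    if labels.shape[0] != n:
        raise ValueError(
            f"partition covers {labels.shape[0]} nodes but the graph has {n}"
        )
    if not weighted:
        A = (A != 0).astype(float)
    k = A.sum(axis=1)
    # k_im: strength of node i into module m, via one matmul with the indicator
    indicator = np.zeros((n, part.module_count))
    indicator[np.arange(n), labels] = 1.0
    k_im = A @ indicator
    pc = np.zeros(n)
    connected = k > 0
    pc[connected] = 1.0 - np.sum((k_im[connected] / k[connected, None]) ** 2, axis=1)
    return pc, float(pc.mean())
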