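"""Independent brute-force oracles used to validate the package implementations.

Everything here is deliberately naive (loops, literal definitions) and never
calls the code paths under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pc_oracle(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Participation coefficient by literal per-module degree recount."""
    n = A.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        k_i = sum(1 for j in range(n) if A[i, j] != 0)
        if k_i == 0:
            continue
        s = 0.0
        for m in set(labels.tolist()):
            k_im = sum(1 for j in range(n) if A[i, j] != 0 and labels[j] == m)
            s += (k_im / k_i) ** 2
        pc[i] = 1.0 - s
    return pc


def nlp_oracle(layers: list[np.ndarray]) -> np.ndarray:
    """Node-degree layer proportion by explicit degree counting."""
    n = layers[0].shape[0]
    M = len(layers)
    nlp = np.zeros((n, M))
    for i in range(n):
        degs = [int(np.sum(layers[lam][i] != 0)) for lam in range(M)]
        o = sum(degs)
        if o > 0:
            nlp[i] = [d / o for d in degs]
    return nlp


def mpc_oracle(layers: list[np.ndarray]) -> np.ndarray:
    """MPC_i by direct formula evaluation on recounted degrees."""
    nlp = nlp_oracle(layers)
    M = len(layers)
    n = nlp.shape[0]
    mpc = np.zeros(n)
    for i in range(n):
        if nlp[i].sum() == 0:
            continue
        mpc[i] = M / (M - 1) * (1.0 - sum(v**2 for v in nlp[i]))
    return mpc


def set_partitions(n: int):
    """All partitions of range(n) via restricted growth strings."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def modularity_value(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity from its definition."""
    A = np.asarray(A, dtype=float)
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A / two_m - np.outer(k, k) / two_m**2
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float(B[same].sum())


def best_modularity_exhaustive(A: np.ndarray) -> float:
    """Global max of modularity over every partition (feasible for n <= 10)."""
    n = A.shape[0]
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A / two_m - np.outer(k, k) / two_m**2
    best = -np.inf
    for labels in set_partitions(n):
        lab = np.array(labels)
        same = lab[:, None] == lab[None, :]
        q = B[same].sum()
        if q > best:
            best = q
    return float(best)


def fdr_stepup_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: sort, find the largest i with
    p_(i) <= i q / m, reject hypotheses 1..i."""
    m = len(p)
    order = sorted(range(m), key=lambda j: p[j])
    cutoff = 0
    for rank, j in enumerate(order, start=1):
        if p[j] <= rank * q / m:
            cutoff = rank
    reject = np.zeros(m, dtype=bool)
    for j in order[:cutoff]:
        reject[j] = True
    return reject


def auc_pairwise_oracle(scores: np.ndarray, labels: np.ndarray, positive) -> float:
    """AUC as the fraction of correctly ordered (positive, negative) pairs,
    ties counted one half (Mann-Whitney)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank-then-Pearson Spearman R, computed without scipy's spearmanr."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def overlap_flatten_oracle(layers: list[np.ndarray]) -> np.ndarray:
    n = layers[0].shape[0]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            out[i, j] = sum(int(L[i, j] != 0) for L in layers)
    return out


def random_multiplex(rng: np.random.Generator, n: int, M: int, p: float = 0.3):
    """Random binary symmetric zero-diagonal layers (for oracle comparisons)."""
    layers = []
    for _ in range(M):
        upper = rng.random((n, n)) < p
        A = np.triu(upper, k=1).astype(np.int8)
        layers.append(A | A.T)
    return layers
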