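"""Network construction: thresholding, binarization, multiplex assembly, flattening.

Weighted band matrices are thresholded to a fixed number of links
``L = round(k * n / 2)`` (round half up) so that every network has average
node degree ``k``, then binarized. Binary layers over the same node set are
assembled into a multiplex with implicit identity inter-layer coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MultiplexNetwork",
    "threshold_to_mean_degree",
    "build_multiplex",
    "flatten_overlapping",
    "flatten_aggregated",
    "edge_density",
    "supra_adjacency",
    "validate_adjacency",
]


def _check_square_symmetric(W: np.ndarray, name: str = "matrix") -> None:
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.isfinite(W).all():
        raise ValueError(f"{name} contains non-finite values")


def validate_adjacency(A: np.ndarray) -> np.ndarray:
    """Validate a binary symmetric zero-diagonal adjacency matrix."""
    A = np.asarray(A)
    _check_square_symmetric(A, "adjacency matrix")
    if not np.all((A == 0) | (A == 1)):
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return A.astype(np.int8)


def threshold_to_mean_degree(W: np.ndarray, k: float) -> np.ndarray:
    """Binarize ``W`` keeping exactly ``L = round(k*n/2)`` strongest edges.

    Ties at the threshold boundary are broken deterministically by sorting
    candidate edges on (weight descending, i ascending, j ascending).

    Parameters
    ----------
    W : (n, n) array
        Symmetric nonnegative weighted matrix with zero diagonal.
    k : float
        Target average node degree; must satisfy
        ``1 <= round(k*n/2) <= n(n-1)/2``.

    Returns
    -------
    (n, n) int8 array — binary symmetric adjacency with exactly L edges.
    """
    W = np.asarray(W, dtype=float)
    _check_square_symmetric(W, "weight matrix")
    if np.any(W < 0):
        raise ValueError("negative weights are not supported (coherence is nonnegative)")
    n = W.shape[0]
    # round half up, robust to float representation of k*n/2
    L = int(np.floor(k * n / 2.0 + 0.5))
    max_edges = n * (n - 1) // 2
    if L < 1 or L > max_edges:
        raise ValueError(
            f"target degree k={k} gives L={L} edges, outside [1, {max_edges}] for n={n}"
        )
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    # lexsort: last key is primary. Want weight desc, then i asc, then j asc.
    order = np.lexsort((ju, iu, -w))
    keep = order[:L]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[keep], ju[keep]] = 1
    A |= A.T
    return A


def edge_density(A: np.ndarray) -> float:
    """Fraction of realized edges: ``2 * edge_count / (n * (n - 1))``."""
    A = validate_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("density undefined for n < 2")
    return float(A.sum() / (n * (n - 1)))


@dataclass(frozen=True)
class MultiplexNetwork:
    """M binary adjacency layers over a common node set.

    Inter-layer coupling is implicit identity (each node is linked to its
    own replicas in every other layer) and is not stored.
    """

    layers: tuple[np.ndarray, ...]
    layer_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multiplex requires M >= 2 layers")
        ns = {layer.shape[0] for layer in self.layers}
        if len(ns) != 1:
            bad = [i for i, l in enumerate(self.layers) if l.shape[0] != self.layers[0].shape[0]]
            raise ValueError(f"layers {bad} have node counts differing from layer 0")
        if self.layer_names and len(self.layer_names) != len(self.layers):
            raise ValueError("layer_names length must match layer count")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def degree_matrix(self) -> np.ndarray:
        """Per-node, per-layer degrees, shape (n_nodes, n_layers)."""
        return np.stack([layer.sum(axis=1) for layer in self.layers], axis=1).astype(float)


def build_multiplex(
    layers: Sequence[np.ndarray], layer_names: Sequence[str] | None = None
) -> MultiplexNetwork:
    """Assemble validated binary layers into a :class:`MultiplexNetwork`.

    Layer order is preserved (band order delta..gamma by convention).
    """
    validated = tuple(validate_adjacency(layer) for layer in layers)
    names = tuple(layer_names) if layer_names is not None else ()
    return MultiplexNetwork(layers=validated, layer_names=names)


def flatten_overlapping(mx: MultiplexNetwork) -> np.ndarray:
    """Edge-count flattening: o_ij = number of layers where (i, j) is linked."""
    return np.sum([layer.astype(int) for layer in mx.layers], axis=0)


def flatten_aggregated(mx: MultiplexNetwork) -> np.ndarray:
    """Union flattening: 1 iff (i, j) linked in at least one layer."""
    return (flatten_overlapping(mx) > 0).astype(np.int8)


def supra_adjacency(mx: MultiplexNetwork) -> np.ndarray:
    """(nM, nM) block matrix: layer adjacencies on the diagonal, identity
    blocks coupling each node to its replicas in every other layer."""
    n, M = mx.n_nodes, mx.n_layers
    S = np.zeros((n * M, n * M), dtype=float)
    eye = np.eye(n)
    for a in range(M):
        for b in range(M):
            block = mx.layers[a] if a == b else eye
            S[a * n : (a + 1) * n, b * n : (b + 1) * n] = block
    return S
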