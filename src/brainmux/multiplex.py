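"""Multiplex node statistics: NLP, multi-participation coefficient, degree CV.

For a node *i* with degree ``k_i[l]`` in layer *l* and overlapping degree
``o_i = sum_l k_i[l]``:

* node-degree layer proportion  NLP_i[l] = k_i[l] / o_i
* multi-participation coefficient
  MPC_i = M/(M-1) * (1 - sum_l NLP_i[l]^2)   (0 if o_i = 0)
* layer-degree coefficient of variation  CV_i = sd_l(k_i) / mean_l(k_i)

Global MPC and CV are plain means over all n nodes, including fully
disconnected ones (which contribute 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .netbuild import MultiplexNetwork

__all__ = [
    "node_degree_layer_proportion",
    "multi_participation_coefficient",
    "layer_degree_cv",
    "node_metric_table",
]


def node_degree_layer_proportion(mx: MultiplexNetwork) -> np.ndarray:
    """Per-node layer proportions of degree, shape (n_nodes, n_layers).

    Rows sum to 1 for nodes with at least one edge in some layer; fully
    disconnected nodes get an all-zero row.
    """
    K = mx.degree_matrix()
    o = K.sum(axis=1)
    nlp = np.zeros_like(K)
    connected = o > 0
    nlp[connected] = K[connected] / o[connected, None]
    return nlp


def multi_participation_coefficient(mx: MultiplexNetwork) -> tuple[np.ndarray, float]:
    """Per-node MPC_i and the global MPC (mean over all nodes).

    MPC_i = 1 when degree is spread evenly over all M layers, 0 when it is
    confined to a single layer. Fully disconnected nodes are assigned 0 to
    avoid the 0/0 indeterminacy.
    """
    M = mx.n_layers
    if M < 2:
        raise ValueError("MPC normalization requires M >= 2 layers")
    nlp = node_degree_layer_proportion(mx)
    mpc = M / (M - 1) * (1.0 - np.sum(nlp**2, axis=1))
    # disconnected rows are all-zero -> sum of squares 0 -> formula gives M/(M-1); fix to 0
    disconnected = ~np.any(nlp > 0, axis=1)
    mpc[disconnected] = 0.0
    return mpc, float(mpc.mean())


def layer_degree_cv(mx: MultiplexNetwork, ddof: int = 0) -> tuple[np.ndarray, float]:
    """Per-node coefficient of variation of degree across layers, and its mean.

    Uses the population sd convention (``ddof=0``) by default; pass
    ``ddof=1`` for the sample convention. Fully disconnected nodes get 0.
    """
    if mx.n_layers < 2:
        raise ValueError("CV across layers requires M >= 2 layers")
    K = mx.degree_matrix()
    mean = K.mean(axis=1)
    sd = K.std(axis=1, ddof=ddof)
    cv = np.zeros_like(mean)
    connected = mean > 0
    cv[connected] = sd[connected] / mean[connected]
    return cv, float(cv.mean())


def node_metric_table(mx: MultiplexNetwork, ddof: int = 0) -> pd.DataFrame:
    """Tabulate o_i, per-layer NLP, MPC_i and CV_i for every node."""
    nlp = node_degree_layer_proportion(mx)
    mpc, _ = multi_participation_coefficient(mx)
    cv, _ = layer_degree_cv(mx, ddof=ddof)
    names = mx.layer_names or tuple(f"layer{i}" for i in range(mx.n_layers))
    data = {"node_id": np.arange(mx.n_nodes), "overlapping_degree": mx.degree_matrix().sum(axis=1)}
    for j, name in enumerate(names):
        data[f"NLP_{name}"] = nlp[:, j]
    data["MPC"] = mpc
    data["CV"] = cv
    return pd.DataFrame(data)
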