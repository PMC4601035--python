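"""Weighted graph indexes for dense coherence networks.

Given a symmetric adjacency ``w`` with weights in [0, 1], edges are assigned
lengths ``l_ij = 1 / w_ij`` (zero-weight pairs have no edge) and four
network indexes are computed:

* ``C``   mean weighted clustering coefficient (geometric-mean triangle
          intensity on the raw weights),
* ``Ge``  global efficiency, the mean of ``1 / d_ij`` over node pairs,
* ``Le``  mean local efficiency (global efficiency of each node's
          neighbour subgraph),
* ``L``   characteristic path length, the mean shortest-path distance.

Raw coherence weights are used without per-graph normalization so that
overall connectivity strength differences between subjects survive into the
indexes; dense matrices are analyzed without thresholding.

For a complete graph with uniform weight ``w`` these definitions give
``C = Ge = Le = w`` and ``L = 1/w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "MetricSet",
    "path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "local_efficiency",
    "metric_set",
]


@dataclass
class MetricSet:
    """The four network indexes plus node-wise values."""

    C: float
    Ge: float
    Le: float
    L: float
    per_node_c: np.ndarray = field(repr=False)
    per_node_le: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {"C": self.C, "Ge": self.Ge, "Le": self.Le, "L": self.L}


def _as_weight_matrix(adj) -> np.ndarray:
    w = np.asarray(getattr(adj, "w", adj), dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return w


def path_lengths(adj) -> np.ndarray:
    """All-pairs shortest-path distances with edge lengths ``1/w``.

    Zero-weight pairs carry no edge; unreachable pairs get ``inf`` and the
    diagonal is 0.
    """
    w = _as_weight_matrix(adj)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(lengths, method="D", directed=False)


def characteristic_path_length(adj, fallback_harmonic: bool = False) -> float:
    """Mean shortest-path distance over all ordered pairs ``i != j``.

    A disconnected graph raises unless ``fallback_harmonic`` is set, in
    which case the harmonic mean ``1 / Ge`` is returned instead (infinite
    distances then contribute zero efficiency rather than poisoning the
    mean).
    """
    d = path_lengths(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        if fallback_harmonic:
            ge = global_efficiency(adj)
            return float(np.inf) if ge == 0 else 1.0 / ge
        raise ValueError(
            "graph is disconnected; characteristic path length undefined "
            "(pass fallback_harmonic=True for the harmonic-mean fallback)"
        )
    return float(d[off].mean())


def global_efficiency(adj) -> float:
    """Mean of ``1/d_ij`` over ordered pairs, with ``1/inf = 0``."""
    d = path_lengths(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[off]), 0.0, 1.0 / d[off])
    return float(inv.mean())


def clustering_coefficient(adj) -> tuple[float, np.ndarray]:
    """Weighted clustering: geometric-mean triangle intensity per node.

    ``C_i = (sum_{j!=h} (w_ij w_jh w_hi)^(1/3)) / (k_i (k_i - 1))`` on the
    raw weights, with ``C_i = 0`` for nodes of degree < 2; the scalar value
    is the node mean.
    """
    w = _as_weight_matrix(adj)
    n = w.shape[0]
    cbrt = np.cbrt(w)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)  # sum over j != h around i
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    per_node = np.zeros(n)
    mask = denom > 0
    per_node[mask] = triangles[mask] / denom[mask]
    return float(per_node.mean()) if n else 0.0, per_node


def local_efficiency(adj) -> tuple[float, np.ndarray]:
    """Global efficiency of each node's neighbour subgraph (node removed)."""
    w = _as_weight_matrix(adj)
    n = w.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        per_node[i] = global_efficiency(w[np.ix_(nb, nb)])
    return float(per_node.mean()) if n else 0.0, per_node


def metric_set(adj, fallback_harmonic: bool = False) -> MetricSet:
    """Compute all four indexes for one adjacency."""
    c, per_c = clustering_coefficient(adj)
    le, per_le = local_efficiency(adj)
    return MetricSet(
        C=c,
        Ge=global_efficiency(adj),
        Le=le,
        L=characteristic_path_length(adj, fallback_harmonic=fallback_harmonic),
        per_node_c=per_c,
        per_node_le=per_le,
    )
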