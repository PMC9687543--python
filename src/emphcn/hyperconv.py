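"""KNN hypergraph construction and normalized hypergraph convolution.

A hypergraph generalizes pairwise edges to hyperedges that join arbitrary
vertex subsets, encoded by a binary incidence matrix H (vertices x
hyperedges).  Here every vertex spawns one hyperedge containing itself
and its K most-similar neighbors, so H is square and each hyperedge has
degree K+1.  The convolution is the degree-normalized two-hop
vertex -> hyperedge -> vertex aggregation

    X' = D_v^{-1/2} H D_e^{-1} H^T D_v^{-1/2} X theta

whose operator is symmetric with spectrum in [0, 1] and exact fixed
point D_v^{1/2} 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .netio import SimilarityView

DEFAULT_K = 15  # neighbors per hyperedge


@dataclass
class Hypergraph:
    """Incidence matrix with cached degree matrices and operator."""

    incidence: np.ndarray
    vertex_degrees: np.ndarray = field(init=False)
    edge_degrees: np.ndarray = field(init=False)
    operator: np.ndarray = field(init=False)

    def __post_init__(self):
        h = np.asarray(self.incidence, dtype=np.float64)
        if not np.all(np.isin(h, [0.0, 1.0])):
            raise ValueError("incidence entries must be binary")
        d_v = h.sum(axis=1)
        d_e = h.sum(axis=0)
        if (d_v < 1).any():
            raise ValueError("isolated vertex (degree 0) in hypergraph")
        if (d_e < 1).any():
            raise ValueError("empty hyperedge in hypergraph")
        self.incidence = h
        self.vertex_degrees = d_v
        self.edge_degrees = d_e
        self.operator = hypergraph_operator_from_parts(h, d_v, d_e)

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.incidence.shape[1]


def build_knn_hypergraph(sim: SimilarityView, k: int = DEFAULT_K,
                         include_center: bool = True) -> Hypergraph:
    """One hyperedge per vertex: the vertex plus its K nearest neighbors.

    Neighbors are ranked by similarity descending with index-ascending
    tie-breaking, so construction is deterministic and seed-free.  K is
    clamped to Nv-1 with a warning for small graphs.  ``include_center``
    keeps the spawning vertex in its own hyperedge (degree K+1); the
    exclusion variant (degree K) is available for sensitivity checks.
    """
    n = len(sim.ids)
    if k < 1:
        raise ValueError("K must be >= 1")
    if k >= n:
        warnings.warn(f"K={k} >= {n} vertices; clamping to {n - 1}")
        k = n - 1
        if k < 1:
            raise ValueError("need at least 2 vertices to build a KNN hypergraph")
    s = np.asarray(sim.matrix, dtype=np.float64)
    h = np.zeros((n, n), dtype=np.float64)
    for v in range(n):
        candidates = [u for u in range(n) if u != v]
        candidates.sort(key=lambda u: (-s[v, u], u))
        members = ([v] if include_center else []) + candidates[:k]
        h[members, v] = 1.0
    return Hypergraph(incidence=h)


def hypergraph_operator_from_parts(h: np.ndarray, d_v: np.ndarray, d_e: np.ndarray) -> np.ndarray:
    dv_isqrt = 1.0 / np.sqrt(d_v)
    # D_v^{-1/2} H D_e^{-1} H^T D_v^{-1/2}, computed with diagonal scaling
    b = (h * dv_isqrt[:, None]) / d_e[None, :]
    op = b @ (h * dv_isqrt[:, None]).T
    return (op + op.T) / 2.0  # enforce exact symmetry against roundoff


def hypergraph_operator(hg: Hypergraph) -> np.ndarray:
    """The cached normalized convolution operator of a hypergraph."""
    return hg.operator


def hgcn_layer(op_matrix, x, theta, activate: bool = True):
    """One hypergraph convolution: act(op @ X @ theta).

    Accepts plain arrays (returns an array) or autodiff Tensors for any
    argument (returns a Tensor); the rectifier is applied when
    ``activate`` is set.  No bias term.
    """
    tensor_mode = any(isinstance(v, ad.Tensor) for v in (op_matrix, x, theta))
    if tensor_mode:
        out = ad.matmul(ad.matmul(ad.as_tensor(op_matrix), ad.as_tensor(x)), ad.as_tensor(theta))
        return ad.relu(out) if activate else out
    out = np.asarray(op_matrix) @ np.asarray(x) @ np.asarray(theta)
    return np.maximum(out, 0.0) if activate else out


def multiview_hgcn(hypergraphs, x, theta, activate: bool = True):
    """Apply the convolution per view with one shared weight matrix.

    Returns a list of per-view outputs (channels).  For plain-array
    inputs the channels are arrays; stack with ``np.stack(..., axis=-1)``
    to obtain the M x F x S channel array.
    """
    n0 = hypergraphs[0].n_vertices
    for hg in hypergraphs:
        if hg.n_vertices != n0:
            raise ValueError("all hypergraphs must share the vertex count")
    return [hgcn_layer(hg.operator, x, theta, activate=activate) for hg in hypergraphs]
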