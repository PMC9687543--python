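"""Inter-domain message passing.

Two routes carry information between drugs and diseases:

* a bipartite graph convolution over the known association matrix that
  element-wise combines neighbor node embeddings with degree-derived
  edge embeddings before projecting across domains (node-and-edge-
  embedding GCN, "NEEGCN"); and
* an attention route through proteins: drug and disease embeddings are
  projected onto proteins with graph attention (GAT), merged, smoothed
  one hop over the protein-protein interaction network, and projected
  back to each domain.

All functions accept plain arrays (returning arrays) or autodiff
Tensors for the learnable arguments (returning Tensors), so the same
code serves both the oracle tests and training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, masked_row_softmax

DEFAULT_LEAKY_SLOPE = 0.2


@dataclass
class EdgeNodeWeights:
    """Learnables of the bipartite node+edge convolution."""

    w_edge_drug: object  # length-F vector
    w_edge_disease: object
    w_d2r: object  # F x F_out cross-domain projections
    w_r2d: object


@dataclass
class AttentionHeadParams:
    """Single attention head: destination/source projections and scorer."""

    w_u: object  # F_dst_in x F_out
    w_v: object  # F_src_in x F_out
    a: object  # (2*F_out, 1) attention vector, split into [a_u; a_v]
    leaky_slope: float = DEFAULT_LEAKY_SLOPE


class EmbeddingState(NamedTuple):
    """Per-domain embeddings at one layer (common feature width)."""

    drugs: object
    diseases: object
    proteins: object = None


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _out(x: Tensor, tensor_mode: bool):
    return x if tensor_mode else x.value


def edge_to_node_features(assoc_matrix, w, axis: str):
    """Degree-scaled edge embedding mapped into the node domain.

    Drug i receives (sum_j A_ij) * w; disease j receives
    (sum_i A_ij) * w, where w is the domain's learnable edge vector.
    """
    a = np.asarray(assoc_matrix.matrix if hasattr(assoc_matrix, "matrix") else assoc_matrix,
                   dtype=np.float64)
    if axis == "drug":
        deg = a.sum(axis=1)
    elif axis == "disease":
        deg = a.sum(axis=0)
    else:
        raise ValueError("axis must be 'drug' or 'disease'")
    tensor_mode = _any_tensor(w)
    wt = ad.as_tensor(w)
    out = ad.mul(Tensor(deg[:, None]), _row(wt))
    return _out(out, tensor_mode)


def _row(v: Tensor) -> Tensor:
    """View a length-F tensor as a 1 x F row (shares gradient)."""
    if v.value.ndim == 2:
        return v
    out = Tensor(v.value[None, :], parents=(v,))

    def backward(grad):
        if v.requires_grad:
            v._accum(grad.reshape(v.value.shape))

    out._backward = backward
    return out


def neegcn_pass(assoc_matrix, x_drugs, x_diseases, x_edge_drug, x_edge_disease,
                weights: EdgeNodeWeights):
    """Symmetric-normalized bipartite convolution with edge embeddings.

    Drug i aggregates, over its associated diseases j,
    (x_d[j] ⊙ x_edge_d[j]) / sqrt(|N_dj| |N_ri|), then projects across
    domains and rectifies; diseases mirror the formula.  Nodes with no
    inter-domain neighbors receive zero (the aggregation is a pure sum).
    """
    a = np.asarray(assoc_matrix.matrix if hasattr(assoc_matrix, "matrix") else assoc_matrix,
                   dtype=np.float64)
    deg_r = a.sum(axis=1)
    deg_d = a.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv_r = np.where(deg_r > 0, 1.0 / np.sqrt(deg_r), 0.0)
        inv_d = np.where(deg_d > 0, 1.0 / np.sqrt(deg_d), 0.0)
    norm = a * inv_r[:, None] * inv_d[None, :]  # M x N, constant per pass

    tensor_mode = _any_tensor(x_drugs, x_diseases, x_edge_drug, x_edge_disease,
                              weights.w_d2r, weights.w_r2d)
    xr, xd = ad.as_tensor(x_drugs), ad.as_tensor(x_diseases)
    er, ed = ad.as_tensor(x_edge_drug), ad.as_tensor(x_edge_disease)
    w_d2r, w_r2d = ad.as_tensor(weights.w_d2r), ad.as_tensor(weights.w_r2d)

    inter_r = ad.relu(ad.matmul(ad.matmul(Tensor(norm), ad.mul(xd, ed)), w_d2r))
    inter_d = ad.relu(ad.matmul(ad.matmul(Tensor(norm.T), ad.mul(xr, er)), w_r2d))
    return _out(inter_r, tensor_mode), _out(inter_d, tensor_mode)


def gat_project(src_x, dst_x, adjacency, params: AttentionHeadParams):
    """Single-head graph attention projecting source onto destination.

    ``adjacency`` is a binary (n_dst x n_src) mask.  Attention over each
    destination's neighborhood is a softmax of leaky-rectified scores
    a^T [W_u x_u || W_v x_v]; the update is rect(sum_j alpha_uj W_v x_j).
    Destinations with no neighbors pass their previous embedding
    through unchanged when widths allow, and get zero rows when the
    layer changes width.
    """
    adj = np.asarray(adjacency, dtype=np.float64)
    tensor_mode = _any_tensor(src_x, dst_x, params.w_u, params.w_v, params.a)
    xs, xd = ad.as_tensor(src_x), ad.as_tensor(dst_x)
    w_u, w_v = ad.as_tensor(params.w_u), ad.as_tensor(params.w_v)
    a_vec = ad.as_tensor(params.a)
    if a_vec.value.ndim == 1:
        a_vec = Tensor(a_vec.value[:, None], parents=(a_vec,))
        parent = a_vec._parents[0]

        def backward(grad, parent=parent):
            if parent.requires_grad:
                parent._accum(grad.reshape(parent.value.shape))

        a_vec._backward = backward
    f_out = w_v.value.shape[1]
    a_u = a_vec[:f_out, :]
    a_v = a_vec[f_out:, :]

    src_proj = ad.matmul(xs, w_v)  # n_src x F_out
    s_dst = ad.matmul(ad.matmul(xd, w_u), a_u)  # n_dst x 1
    s_src = ad.matmul(src_proj, a_v)  # n_src x 1
    scores = ad.leaky_relu(ad.add(s_dst, s_src.T), slope=params.leaky_slope)
    alpha = masked_row_softmax(scores, adj)
    updated = ad.relu(ad.matmul(alpha, src_proj))

    has_nbr = (adj.sum(axis=1) > 0).astype(np.float64)[:, None]
    if xd.value.shape[1] == f_out:
        out = ad.add(ad.mul(Tensor(has_nbr), updated),
                     ad.mul(Tensor(1.0 - has_nbr), xd))
    else:
        out = ad.mul(Tensor(has_nbr), updated)
    return _out(out, tensor_mode)


def gat_attention_coefficients(src_x, dst_x, adjacency, params: AttentionHeadParams) -> np.ndarray:
    """The attention matrix alpha (n_dst x n_src) as plain numbers."""
    adj = np.asarray(adjacency, dtype=np.float64)
    xs = np.asarray(src_x.value if isinstance(src_x, Tensor) else src_x, dtype=np.float64)
    xd = np.asarray(dst_x.value if isinstance(dst_x, Tensor) else dst_x, dtype=np.float64)
    w_u = np.asarray(params.w_u.value if isinstance(params.w_u, Tensor) else params.w_u)
    w_v = np.asarray(params.w_v.value if isinstance(params.w_v, Tensor) else params.w_v)
    a = np.asarray(params.a.value if isinstance(params.a, Tensor) else params.a).reshape(-1, 1)
    f_out = w_v.shape[1]
    s = (xd @ w_u @ a[:f_out]) + (xs @ w_v @ a[f_out:]).T
    s = np.where(s > 0, s, params.leaky_slope * s)
    s = np.where(adj > 0, s, -np.inf)
    with np.errstate(invalid="ignore"):
        e = np.exp(s - np.nanmax(np.where(adj > 0, s, np.nan), axis=1, keepdims=True,
                                 initial=-np.inf))
    e = np.where(adj > 0, e, 0.0)
    denom = e.sum(axis=1, keepdims=True)
    return np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)


@dataclass
class ProteinBranchParams:
    """Per-layer parameters of the protein-mediated route."""

    r2p: AttentionHeadParams
    d2p: AttentionHeadParams
    p2p: AttentionHeadParams
    p2r: AttentionHeadParams
    p2d: AttentionHeadParams
    ep_proj: object  # 2F_out x F_out merge of the two protein projections
    faithful_printed_asymmetry: bool = False


class ProteinMessages(NamedTuple):
    x_p_r: object  # M x F_out contribution to drugs
    x_p_d: object  # N x F_out contribution to diseases
    protein_state: object  # P x F_out smoothed protein embedding


def protein_message_round(state: EmbeddingState, drug_protein_adj, disease_protein_adj,
                          ppi_adj, params: ProteinBranchParams) -> ProteinMessages:
    """One full drug/disease -> protein -> PPI -> drug/disease round.

    Drug and disease embeddings are attention-projected onto proteins,
    merged by feature-axis concatenation plus a learnable 2F -> F map,
    smoothed one GAT hop over the PPI graph, and attention-projected
    back to both domains.  Proteins with neighbors on only one side are
    determined by that side alone (the other projection contributes a
    zero block).  ``faithful_printed_asymmetry`` projects the unsmoothed
    protein embedding back to drugs (a variant kept for comparison).
    """
    if state.proteins is None:
        raise ValueError("protein branch requires a protein embedding state")
    dp = np.asarray(drug_protein_adj, dtype=np.float64)  # M x P
    sp = np.asarray(disease_protein_adj, dtype=np.float64)  # N x P
    pp = np.asarray(ppi_adj, dtype=np.float64)  # P x P

    e_r2p = gat_project(state.drugs, state.proteins, dp.T, params.r2p)
    e_d2p = gat_project(state.diseases, state.proteins, sp.T, params.d2p)
    tensor_mode = _any_tensor(e_r2p, e_d2p, params.ep_proj)
    e_p = ad.matmul(ad.concat([ad.as_tensor(e_r2p), ad.as_tensor(e_d2p)], axis=1),
                    ad.as_tensor(params.ep_proj))
    e_p_smooth = ad.as_tensor(gat_project(e_p, e_p, pp, params.p2p))
    back_src = e_p if params.faithful_printed_asymmetry else e_p_smooth
    x_p_r = gat_project(back_src, state.drugs, dp, params.p2r)
    x_p_d = gat_project(e_p_smooth, state.diseases, sp, params.p2d)
    return ProteinMessages(
        x_p_r if tensor_mode else _strip(x_p_r),
        x_p_d if tensor_mode else _strip(x_p_d),
        e_p_smooth if tensor_mode else _strip(e_p_smooth),
    )


def _strip(x):
    return x.value if isinstance(x, Tensor) else x


def drop_edges(adjacency: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli edge removal before normalization constants."""
    if rate <= 0:
        return adjacency
    keep = rng.random(adjacency.shape) >= rate
    return adjacency * keep
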