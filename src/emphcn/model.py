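"""The full drug-repositioning model.

Two hidden layers, each fusing three embedding routes per domain:

* intra-domain — hypergraph convolution over KNN hypergraphs built from
  the similarity matrices, with efficient channel attention fusing the
  multiple drug views;
* inter-domain — bipartite node+edge graph convolution over the known
  drug-disease associations;
* protein route — graph attention through the drug-protein-disease
  network with one PPI smoothing hop (optional).

The fused first- and second-layer embeddings are combined by a skip
connection (with a learnable width projection, since the layers have
different widths) and scored as logistic(X_r X_d^T).  Training minimizes
a class-balanced binary cross-entropy with Adam, full-batch, with
per-epoch edge dropout on the association and protein graphs and
feature dropout on the fused embeddings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import attention_fusion as af
from . import autodiff as ad
from . import hyperconv as hc
from . import message_passing as mp
from .autodiff import Adam, Tensor
from .netio import AssociationMatrix, HeteroNetwork

logger = logging.getLogger(__name__)

EPS = 1e-12  # clamp inside the loss logs


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the reference setting at full
    dataset scale (hidden widths 256/128, lr 0.002, feature dropout 0.4)."""

    k1: int = 256
    k2: int = 128
    lr: float = 0.002
    beta: float = 0.4  # feature dropout on fused embeddings
    gamma: float = 0.35  # edge dropout on association + protein graphs
    epochs: int = 4500
    knn_k: int = 15
    eca_kernel: int = 3
    seed: int = 0
    use_hgcn: bool = True  # False: plain GCN over the KNN graph (ablation)
    use_multiview_attention: bool = True  # False: single-view intra route
    use_protein_branch: bool = True
    faithful_eq14: bool = False  # printed protein->drug asymmetry variant
    initial_view_index: int = 0
    hgcn_activation: bool = True
    per_view_weights: bool = False
    include_center: bool = True  # vertex belongs to its own hyperedge
    literal_skip_sum: bool = False  # requires k1 == k2

    def __post_init__(self):
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("hidden widths must be >= 1")
        for name in ("beta", "gamma"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0,1)")
        if self.literal_skip_sum and self.k1 != self.k2:
            raise ValueError("literal skip sum requires k1 == k2")


def small_config(**overrides) -> ModelConfig:
    """Compact setting for simulated networks of a few dozen entities."""
    base = dict(k1=64, k2=32, lr=0.01, beta=0.1, gamma=0.1, epochs=500)
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class LossSpec:
    """Index sets and balance factor of the weighted cross-entropy."""

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    lambda_balance: float = field(init=False)

    def __post_init__(self):
        self.positive_mask = np.asarray(self.positive_mask, dtype=np.float64)
        self.negative_mask = np.asarray(self.negative_mask, dtype=np.float64)
        if (self.positive_mask * self.negative_mask).any():
            raise ValueError("positive and negative sets must be disjoint")
        n_pos = self.positive_mask.sum()
        if n_pos == 0:
            raise ValueError("no positive training pairs")
        self.lambda_balance = float(self.negative_mask.sum() / n_pos)


def weighted_bce_loss(scores, assoc, spec: LossSpec):
    """Class-balanced BCE: -(1/(N M)) [lambda sum_y log s + sum_ybar log(1-s)].

    ``assoc`` is accepted for interface symmetry (the masks in ``spec``
    already encode which pairs are positive/negative).  Scores exactly 0
    or 1 are guarded by an epsilon clamp inside the logs only.
    """
    tensor_mode = isinstance(scores, Tensor)
    s = ad.as_tensor(scores)
    m, n = s.value.shape
    pos = Tensor(spec.positive_mask)
    neg = Tensor(spec.negative_mask)
    log_s = ad.log(ad.clip(s, EPS, 1.0 - EPS))
    log_1ms = ad.log(ad.clip(ad.add(1.0, ad.mul(s, -1.0)), EPS, 1.0 - EPS))
    total = ad.add(
        ad.mul(ad.tensor_sum(ad.mul(pos, log_s)), spec.lambda_balance),
        ad.tensor_sum(ad.mul(neg, log_1ms)),
    )
    loss = ad.mul(total, -1.0 / (m * n))
    return loss if tensor_mode else float(loss.value)


def weighted_bce_from_logits(logits, spec: LossSpec):
    """The same balanced cross-entropy computed from pre-activation
    logits via a stable log-sigmoid, so gradients survive score
    saturation (training-path variant of :func:`weighted_bce_loss`)."""
    x = ad.as_tensor(logits)
    m, n = x.value.shape
    pos = Tensor(spec.positive_mask)
    neg = Tensor(spec.negative_mask)
    total = ad.add(
        ad.mul(ad.tensor_sum(ad.mul(pos, ad.log_sigmoid(x))), spec.lambda_balance),
        ad.tensor_sum(ad.mul(neg, ad.log_sigmoid(ad.mul(x, -1.0)))),
    )
    return ad.mul(total, -1.0 / (m * n))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class EMPHCN:
    """Model instance bound to one heterogeneous network."""

    def __init__(self, network: HeteroNetwork, cfg: ModelConfig):
        self.network = network
        self.cfg = cfg
        m, n = network.n_drugs, network.n_diseases
        if not 0 <= cfg.initial_view_index < len(network.drug_views):
            raise ValueError("initial_view_index out of range")

        self.drug_hypergraphs = [
            hc.build_knn_hypergraph(v, cfg.knn_k, include_center=cfg.include_center)
            for v in network.drug_views.views
        ]
        self.disease_hypergraph = hc.build_knn_hypergraph(
            network.disease_sim, cfg.knn_k, include_center=cfg.include_center
        )
        if cfg.use_hgcn:
            self.drug_ops = [hg.operator for hg in self.drug_hypergraphs]
            self.disease_op = self.disease_hypergraph.operator
        else:  # ablation: symmetric-normalized simple-graph convolution
            self.drug_ops = [
                _gcn_operator(hg.incidence) for hg in self.drug_hypergraphs
            ]
            self.disease_op = _gcn_operator(self.disease_hypergraph.incidence)

        self.x_r0, self.x_d0 = self.initial_inputs()
        self.protein_enabled = cfg.use_protein_branch and network.has_protein_branch
        if self.protein_enabled:
            self.dp_adj = network.drug_protein_adjacency().astype(np.float64)
            self.sp_adj = network.disease_protein_adjacency().astype(np.float64)
            self.pp_adj = network.ppi_adjacency().astype(np.float64)
            self.x_p0 = np.eye(network.n_proteins)
        self.params = self._init_params(np.random.default_rng(cfg.seed))
        self.training_log: list[dict] = []

    # -- construction ---------------------------------------------------
    def initial_inputs(self) -> tuple[np.ndarray, np.ndarray]:
        """Incidence matrices of the configured drug view and the disease
        hypergraph serve as initial features for both branches."""
        return (
            self.drug_hypergraphs[self.cfg.initial_view_index].incidence.copy(),
            self.disease_hypergraph.incidence.copy(),
        )

    def _layer_widths(self):
        m, n = self.network.n_drugs, self.network.n_diseases
        p = self.network.n_proteins
        return [
            {"r": m, "d": n, "p": p, "out": self.cfg.k1},
            {"r": self.cfg.k1, "d": self.cfg.k1, "p": self.cfg.k1, "out": self.cfg.k2},
        ]

    def _init_params(self, rng) -> dict[str, Tensor]:
        cfg = self.cfg
        s_views = len(self.drug_ops)
        params: dict[str, np.ndarray] = {}
        for l, w in enumerate(self._layer_widths(), start=1):
            if cfg.per_view_weights:
                for s in range(s_views):
                    params[f"theta_intra_r_{l}_view{s}"] = _glorot(rng, (w["r"], w["out"]))
            else:
                params[f"theta_intra_r_{l}"] = _glorot(rng, (w["r"], w["out"]))
            params[f"theta_intra_d_{l}"] = _glorot(rng, (w["d"], w["out"]))
            if s_views > 1 and cfg.use_multiview_attention:
                params[f"eca_kernel_{l}"] = rng.uniform(-0.01, 0.01, size=cfg.eca_kernel)
            # edge vectors start at one: the pass then reduces to a plain
            # symmetric-normalized bipartite convolution at initialization
            params[f"w_edge_drug_{l}"] = np.ones(w["r"])
            params[f"w_edge_disease_{l}"] = np.ones(w["d"])
            params[f"w_d2r_{l}"] = _glorot(rng, (w["d"], w["out"]))
            params[f"w_r2d_{l}"] = _glorot(rng, (w["r"], w["out"]))
            if self.protein_enabled:
                heads = {
                    "r2p": (w["p"], w["r"]),
                    "d2p": (w["p"], w["d"]),
                    "p2p": (w["out"], w["out"]),
                    "p2r": (w["r"], w["out"]),
                    "p2d": (w["d"], w["out"]),
                }
                for name, (f_dst, f_src) in heads.items():
                    params[f"{name}_wu_{l}"] = _glorot(rng, (f_dst, w["out"]))
                    params[f"{name}_wv_{l}"] = _glorot(rng, (f_src, w["out"]))
                    params[f"{name}_a_{l}"] = _glorot(rng, (2 * w["out"], 1))
                params[f"ep_proj_{l}"] = _glorot(rng, (2 * w["out"], w["out"]))
        if not cfg.literal_skip_sum:
            params["skip_r"] = np.zeros((cfg.k1, cfg.k2))
            params["skip_d"] = np.zeros((cfg.k1, cfg.k2))
        return {k: Tensor(v, requires_grad=True, name=k) for k, v in params.items()}

    # -- forward --------------------------------------------------------
    def forward(self, a_train: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        """Score all drug-disease pairs; returns an M x N Tensor in (0,1)."""
        cfg, p = self.cfg, self.params
        a = np.asarray(a_train, dtype=np.float64)
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")

        if training and cfg.gamma > 0:
            a = mp.drop_edges(a, cfg.gamma, rng)
        if self.protein_enabled:
            dp, sp, pp = self.dp_adj, self.sp_adj, self.pp_adj
            if training and cfg.gamma > 0:
                dp = mp.drop_edges(dp, cfg.gamma, rng)
                sp = mp.drop_edges(sp, cfg.gamma, rng)
                keep = np.triu(rng.random(pp.shape) >= cfg.gamma, 1)
                pp = pp * (keep + keep.T)

        x_r, x_d = Tensor(self.x_r0), Tensor(self.x_d0)
        x_p = Tensor(self.x_p0) if self.protein_enabled else None
        layer_embeddings = []
        for l in (1, 2):
            # intra-domain route
            if cfg.per_view_weights:
                channels = [
                    hc.hgcn_layer(op, x_r, p[f"theta_intra_r_{l}_view{s}"],
                                  activate=cfg.hgcn_activation)
                    for s, op in enumerate(self.drug_ops)
                ]
            else:
                channels = [
                    hc.hgcn_layer(op, x_r, p[f"theta_intra_r_{l}"],
                                  activate=cfg.hgcn_activation)
                    for op in self.drug_ops
                ]
            if len(channels) == 1:
                x_intra_r = channels[0]
            elif cfg.use_multiview_attention:
                omega = af.eca_weights(af.global_average_pool(channels),
                                       p[f"eca_kernel_{l}"])
                x_intra_r = af.fuse_channels(channels, omega)
            else:  # single-view ablation: use the configured view only
                x_intra_r = channels[cfg.initial_view_index]
            x_intra_d = hc.hgcn_layer(self.disease_op, x_d, p[f"theta_intra_d_{l}"],
                                      activate=cfg.hgcn_activation)

            # inter-domain route over known associations
            edge_r = mp.edge_to_node_features(a, p[f"w_edge_drug_{l}"], "drug")
            edge_d = mp.edge_to_node_features(a, p[f"w_edge_disease_{l}"], "disease")
            weights = mp.EdgeNodeWeights(
                w_edge_drug=p[f"w_edge_drug_{l}"],
                w_edge_disease=p[f"w_edge_disease_{l}"],
                w_d2r=p[f"w_d2r_{l}"],
                w_r2d=p[f"w_r2d_{l}"],
            )
            x_inter_r, x_inter_d = mp.neegcn_pass(a, x_r, x_d, edge_r, edge_d, weights)

            new_r = ad.add(x_intra_r, x_inter_r)
            new_d = ad.add(x_intra_d, x_inter_d)
            if self.protein_enabled:
                branch = mp.ProteinBranchParams(
                    r2p=self._head("r2p", l), d2p=self._head("d2p", l),
                    p2p=self._head("p2p", l), p2r=self._head("p2r", l),
                    p2d=self._head("p2d", l), ep_proj=p[f"ep_proj_{l}"],
                    faithful_printed_asymmetry=cfg.faithful_eq14,
                )
                msgs = mp.protein_message_round(
                    mp.EmbeddingState(x_r, x_d, x_p), dp, sp, pp, branch
                )
                new_r = ad.add(new_r, msgs.x_p_r)
                new_d = ad.add(new_d, msgs.x_p_d)
                x_p = ad.as_tensor(msgs.protein_state)

            if training and cfg.beta > 0:  # feature dropout after fusion
                new_r = ad.mul(new_r, Tensor(self._dropout_mask(rng, new_r.shape)))
                new_d = ad.mul(new_d, Tensor(self._dropout_mask(rng, new_d.shape)))
            x_r, x_d = new_r, new_d
            layer_embeddings.append((x_r, x_d))

        (r1, d1), (r2, d2) = layer_embeddings
        if cfg.literal_skip_sum:
            hat_r, hat_d = ad.add(r1, r2), ad.add(d1, d2)
        else:
            hat_r = ad.add(ad.matmul(r1, p["skip_r"]), r2)
            hat_d = ad.add(ad.matmul(d1, p["skip_d"]), d2)
        logits = ad.matmul(hat_r, hat_d.T)
        scores = ad.sigmoid(logits)
        if np.isnan(scores.value).any():
            raise FloatingPointError("NaN in forward pass scores")
        self._last_logits = logits
        return scores

    def _head(self, name: str, l: int) -> mp.AttentionHeadParams:
        p = self.params
        return mp.AttentionHeadParams(
            w_u=p[f"{name}_wu_{l}"], w_v=p[f"{name}_wv_{l}"], a=p[f"{name}_a_{l}"]
        )

    def _dropout_mask(self, rng, shape):
        keep = 1.0 - self.cfg.beta
        return (rng.random(shape) < keep) / keep

    # -- training -------------------------------------------------------
    def fit(self, a_train: Optional[np.ndarray] = None,
            loss_spec: Optional[LossSpec] = None,
            epochs: Optional[int] = None) -> list[dict]:
        """Full-batch Adam training; returns the per-epoch log."""
        cfg = self.cfg
        if a_train is None:
            a_train = self.network.assoc.matrix.astype(np.float64)
        if loss_spec is None:
            loss_spec = LossSpec(
                positive_mask=(a_train > 0), negative_mask=(a_train == 0)
            )
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 77_003)
        opt = Adam(self.params, lr=cfg.lr)
        self.training_log = []
        for epoch in range(epochs):
            opt.zero_grad()
            self.forward(a_train, training=True, rng=rng)
            loss = weighted_bce_from_logits(self._last_logits, loss_spec)
            loss.backward()
            opt.step()
            entry = {"epoch": epoch, "loss": float(loss.value)}
            self.training_log.append(entry)
            if epoch % 100 == 0:
                logger.info("epoch %d loss %.6f", epoch, float(loss.value))
            if np.isnan(loss.value):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
        return self.training_log

    def predict(self, a_train: Optional[np.ndarray] = None) -> np.ndarray:
        """Deterministic eval-mode score matrix as plain numbers."""
        if a_train is None:
            a_train = self.network.assoc.matrix.astype(np.float64)
        return self.forward(a_train, training=False).value

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{k: v.value for k, v in self.params.items()})
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.cfg), "format_version": 1})
        )

    def load_params(self, path) -> None:
        archive = np.load(Path(path).with_suffix(".npz"))
        for k, v in self.params.items():
            v.value = np.asarray(archive[k], dtype=np.float64)


def _gcn_operator(incidence: np.ndarray) -> np.ndarray:
    """Plain-graph stand-in for the hypergraph operator (ablation):
    symmetric normalization of the symmetrized KNN adjacency + self-loops."""
    adj = ((incidence + incidence.T) > 0).astype(np.float64)
    np.fill_diagonal(adj, 1.0)
    deg = adj.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    return adj * d_isqrt[:, None] * d_isqrt[None, :]


def rank_candidates(scores: np.ndarray, query: str, drug_ids: list[str],
                    disease_ids: list[str], exclude_known: bool = False,
                    assoc: Optional[AssociationMatrix] = None) -> list[tuple[str, float]]:
    """Rank partners of a drug or disease by descending score (ties by
    id order); known positives optionally excluded."""
    scores = np.asarray(scores)
    if query in drug_ids:
        i = drug_ids.index(query)
        col = scores[i, :]
        ids = disease_ids
        known = set(np.nonzero(assoc.matrix[i, :])[0]) if exclude_known else set()
    elif query in disease_ids:
        j = disease_ids.index(query)
        col = scores[:, j]
        ids = drug_ids
        known = set(np.nonzero(assoc.matrix[:, j])[0]) if exclude_known else set()
    else:
        raise KeyError(f"unknown id {query!r}")
    if exclude_known and assoc is None:
        raise ValueError("exclude_known requires the association matrix")
    order = sorted(range(len(ids)), key=lambda t: (-col[t], t))
    return [(ids[t], float(col[t])) for t in order if t not in known]
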