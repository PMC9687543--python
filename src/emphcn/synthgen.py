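"""Synthetic heterogeneous networks with planted low-rank structure.

Drugs and diseases receive latent factor rows U (M x r) and V (N x r);
associations are Bernoulli draws from logistic(U V^T + b) with the
offset b calibrated so the expected positive fraction hits the target
density.  Similarity views are noisy logistic transforms of the drug
factor correlation kernel, so all views are consistent with one shared
latent structure and differ only by noise.  Protein links are drawn
with probabilities increasing in the alignment between entity factors
and per-protein latent directions, which correlates the protein layer
with the association structure it is meant to help recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import netio
from .netio import (
    AssociationMatrix,
    BipartiteEdgeList,
    HeteroNetwork,
    MultiViewSimilaritySet,
    PPINetwork,
    SimilarityView,
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the seed fully determines the output."""

    m: int = 60
    n: int = 80
    p: int = 100
    s: int = 3
    rank: int = 4
    density: float = 0.08
    view_noise: float = 0.3
    protein_link_prob: Optional[float] = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.rank > min(self.m, self.n):
            raise ValueError("rank must not exceed min(M, N)")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0,1)")


@dataclass
class SynthTruth:
    """Planted factors and the full association probability matrix."""

    u: np.ndarray
    v: np.ndarray
    full_prob: np.ndarray


def _drug_ids(m: int) -> list[str]:
    return [f"drug{i:03d}" for i in range(m)]


def _disease_ids(n: int) -> list[str]:
    return [f"dis{i:03d}" for i in range(n)]


def _protein_ids(p: int) -> list[str]:
    return [f"prot{i:03d}" for i in range(p)]


def generate_latent_factors(cfg: SynthConfig) -> SynthTruth:
    """Standard-normal factors; offset b calibrated by bisection so that
    mean(logistic(U V^T + b)) equals the target density within 1e-3."""
    rng = np.random.default_rng(cfg.seed)
    u = rng.standard_normal((cfg.m, cfg.rank))
    v = rng.standard_normal((cfg.n, cfg.rank))
    logits = u @ v.T

    def excess(b):
        return expit(logits + b).mean() - cfg.density

    lo, hi = -50.0, 50.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise RuntimeError("density calibration failed to bracket")
    b = brentq(excess, lo, hi, xtol=1e-6)
    full_prob = expit(logits + b)
    if abs(full_prob.mean() - cfg.density) > 1e-3:
        raise RuntimeError("density calibration did not converge")
    return SynthTruth(u=u, v=v, full_prob=full_prob)


def generate_association_matrix(truth: SynthTruth, seed: int,
                                max_retries: int = 100) -> AssociationMatrix:
    """Bernoulli draws from the planted probabilities.

    Every drug and disease must end up with at least one association
    (the model assumes every node has some context).  All-zero rows are
    redrawn individually, conditioned on at least one positive; any
    still-empty column then receives its most probable association.
    Low-probability rows can exhaust the per-row retry budget, which is
    an error (the configuration is degenerate).
    """
    m, n = truth.full_prob.shape
    if truth.full_prob.max() <= 0.0:
        raise RuntimeError("retries exhausted: association probabilities are all zero")
    rng = np.random.default_rng(seed)
    a = (rng.random((m, n)) < truth.full_prob).astype(np.int8)
    for i in range(m):
        tries = 0
        while a[i].sum() == 0:
            if tries >= max_retries:
                raise RuntimeError(
                    f"row {i}: no positive draw in {max_retries} retries"
                )
            a[i] = rng.random(n) < truth.full_prob[i]
            tries += 1
    for j in range(n):
        if a[:, j].sum() == 0:
            a[int(np.argmax(truth.full_prob[:, j])), j] = 1
    return AssociationMatrix(
        drug_ids=_drug_ids(m), disease_ids=_disease_ids(n), matrix=a
    )


def similarity_kernel(u: np.ndarray) -> np.ndarray:
    """Noise-free drug similarity: logistic of the factor correlation.

    Rows of U are centered and normalized (a correlation-style kernel in
    [-1,1]) then mapped through a logistic with gain 3 so similar drugs
    approach 1 and anti-correlated drugs approach 0.
    """
    centered = u - u.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = (centered / norms) @ (centered / norms).T
    corr = (corr + corr.T) / 2.0  # exact bitwise symmetry
    return expit(3.0 * corr)


def generate_similarity_views(truth: SynthTruth, cfg: SynthConfig) -> MultiViewSimilaritySet:
    """S noisy views of the shared kernel: symmetric, unit diagonal, [0,1]."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    kernel = similarity_kernel(truth.u)
    views = []
    for _ in range(cfg.s):
        noise = rng.standard_normal(kernel.shape) * cfg.view_noise * 0.1
        mat = kernel + (noise + noise.T) / 2.0
        np.fill_diagonal(mat, 1.0)
        mat = np.clip(mat, 0.0, 1.0)
        views.append(SimilarityView(ids=_drug_ids(cfg.m), matrix=mat))
    return MultiViewSimilaritySet(views=views)


def generate_disease_similarity(truth: SynthTruth, cfg: SynthConfig) -> SimilarityView:
    """Single disease view from the disease factor kernel (no noise)."""
    mat = similarity_kernel(truth.v)
    np.fill_diagonal(mat, 1.0)
    return SimilarityView(ids=_disease_ids(cfg.n), matrix=np.clip(mat, 0.0, 1.0))


def generate_protein_layer(truth: SynthTruth, cfg: SynthConfig):
    """Protein links correlated with the planted factors.

    Each protein gets a unit latent direction; an entity links to it
    with probability logistic(2 * factor-direction alignment) scaled to
    [floor, 1], floored at ``protein_link_prob``.  PPI edges connect
    proteins with similar directions; each protein is guaranteed at
    least one PPI partner (nearest-direction fallback).
    """
    if cfg.p < cfg.rank:
        raise ValueError("need at least `rank` proteins")
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    dirs = rng.standard_normal((cfg.p, truth.u.shape[1]))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    floor = cfg.protein_link_prob

    pids = _protein_ids(cfg.p)

    def draw_edges(factors, ids):
        align = expit(2.0 * (factors @ dirs.T))
        if floor >= 1.0:
            prob = np.ones_like(align)
        elif floor == 0.0:
            # no floor: only clearly aligned pairs link (orthogonal -> near-empty)
            prob = np.clip((align - 0.5) * 2.0, 0.0, 1.0)
        else:
            prob = floor + (1.0 - floor) * align
        mask = rng.random(prob.shape) < prob
        return [(ids[i], pids[j]) for i, j in zip(*np.nonzero(mask))]

    drug_edges = draw_edges(truth.u, _drug_ids(cfg.m))
    disease_edges = draw_edges(truth.v, _disease_ids(cfg.n))

    sim = dirs @ dirs.T
    ppi_pairs: set[tuple[int, int]] = set()
    for i in range(cfg.p):
        for j in range(i + 1, cfg.p):
            if rng.random() < expit(6.0 * (sim[i, j] - 0.5)):
                ppi_pairs.add((i, j))
    for i in range(cfg.p):  # guarantee a partner: closest direction
        if not any(i in pair for pair in ppi_pairs):
            order = np.argsort(-sim[i])
            j = next(int(x) for x in order if x != i)
            ppi_pairs.add((min(i, j), max(i, j)))
    ppi = PPINetwork(protein_ids=pids,
                     edges=[(pids[i], pids[j]) for i, j in sorted(ppi_pairs)])
    return (
        BipartiteEdgeList("drug", "protein", drug_edges),
        BipartiteEdgeList("disease", "protein", disease_edges),
        ppi,
    )


def generate_dataset(cfg: SynthConfig) -> tuple[HeteroNetwork, SynthTruth]:
    """Compose the generators and assemble a validated network.

    ``protein_link_prob=None`` disables the protein layer entirely,
    mirroring datasets that ship without protein annotations.
    """
    truth = generate_latent_factors(cfg)
    assoc = generate_association_matrix(truth, seed=cfg.seed + 500_009)
    drug_views = generate_similarity_views(truth, cfg)
    disease_sim = generate_disease_similarity(truth, cfg)
    if cfg.protein_link_prob is None:
        network = netio.assemble_network(drug_views, disease_sim, assoc)
    else:
        dp, sp, ppi = generate_protein_layer(truth, cfg)
        network = netio.assemble_network(drug_views, disease_sim, assoc, dp, sp, ppi)
    return network, truth


def write_dataset(network: HeteroNetwork, truth: SynthTruth, out_dir) -> None:
    """Write the network in the standard file formats plus a truth sidecar."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, view in enumerate(network.drug_views.views):
        netio.write_similarity_matrix(view, out / f"drug_similarity_view{i}.tsv")
    netio.write_similarity_matrix(network.disease_sim, out / "disease_similarity.tsv")
    netio.write_association_matrix(network.assoc, out / "associations.tsv")
    if network.has_protein_branch:
        netio.write_edge_list(network.drug_protein.edges, out / "drug_protein.tsv")
        netio.write_edge_list(network.disease_protein.edges, out / "disease_protein.tsv")
        netio.write_edge_list(network.ppi.edges, out / "ppi.tsv")
    (out / "truth.json").write_text(json.dumps({
        "u": truth.u.tolist(),
        "v": truth.v.tolist(),
        "full_prob": truth.full_prob.tolist(),
    }))
    netio.write_validation_report(network, out / "validation_report.json")


def load_dataset(in_dir) -> HeteroNetwork:
    """Re-load a dataset written by :func:`write_dataset`."""
    from pathlib import Path

    d = Path(in_dir)
    views = sorted(d.glob("drug_similarity_view*.tsv"))
    drug_views = MultiViewSimilaritySet(
        views=[netio.load_similarity_matrix(p) for p in views]
    )
    disease_sim = netio.load_similarity_matrix(d / "disease_similarity.tsv")
    assoc = netio.load_association_matrix(d / "associations.tsv")
    if (d / "ppi.tsv").exists():
        dp = netio.load_edge_list(d / "drug_protein.tsv", "drug", "protein")
        sp = netio.load_edge_list(d / "disease_protein.tsv", "disease", "protein")
        ppi_edges = netio.load_edge_list(d / "ppi.tsv", "protein", "protein")
        pids = sorted({x for e in ppi_edges.edges for x in e})
        ppi = PPINetwork(protein_ids=pids, edges=ppi_edges.edges)
        return netio.assemble_network(drug_views, disease_sim, assoc, dp, sp, ppi)
    return netio.assemble_network(drug_views, disease_sim, assoc)
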