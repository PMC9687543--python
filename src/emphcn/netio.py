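"""Reading, validation and assembly of the heterogeneous drug-disease network.

The network couples three entity domains — drugs, diseases and proteins —
through six graphs: multiple drug-drug similarity views, one
disease-disease similarity matrix, the known binary drug-disease
association matrix, and (optionally) drug-protein and disease-protein
bipartite edge lists plus a protein-protein interaction (PPI) graph.
Similarity matrices arrive as delimited text with identifier headers;
edge lists as two/three-column TSV.  Everything downstream indexes
entities by position, so identifier alignment is resolved here, once.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ASYMMETRY_TOL = 1e-6
_CLIP_TOL = 1e-6


@dataclass
class SimilarityView:
    """A square symmetric similarity matrix in [0,1] with unit diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.matrix.shape} does not match {n} ids"
            )

    def validate(self, tol: float = 1e-8) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=tol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=tol):
            raise ValueError("similarity diagonal is not 1")
        if self.matrix.min() < -tol or self.matrix.max() > 1 + tol:
            raise ValueError("similarity values outside [0,1]")


@dataclass
class MultiViewSimilaritySet:
    """Ordered drug similarity views sharing one id registry."""

    views: list[SimilarityView]

    def __post_init__(self):
        if len(self.views) < 1:
            raise ValueError("at least one similarity view required")
        ids0 = self.views[0].ids
        for v in self.views[1:]:
            if v.ids != ids0:
                raise ValueError("similarity views disagree on drug ids")

    @property
    def ids(self) -> list[str]:
        return self.views[0].ids

    def __len__(self) -> int:
        return len(self.views)


@dataclass
class AssociationMatrix:
    """Binary drug-disease association matrix A (M drugs x N diseases)."""

    drug_ids: list[str]
    disease_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match id counts")
        uniq = np.unique(self.matrix)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("association matrix entries must be 0/1")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def n_positive(self) -> int:
        return int(self.matrix.sum())


@dataclass
class BipartiteEdgeList:
    source_domain: str
    target_domain: str
    edges: list[tuple[str, str]]

    def __post_init__(self):
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in bipartite edge list")


@dataclass
class PPINetwork:
    """Undirected unit-weight protein-protein interaction edges."""

    protein_ids: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self):
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on protein {a}")


@dataclass
class HeteroNetwork:
    """All graphs of the multi-association network with aligned indices."""

    drug_views: MultiViewSimilaritySet
    disease_sim: SimilarityView
    assoc: AssociationMatrix
    drug_protein: Optional[BipartiteEdgeList] = None
    disease_protein: Optional[BipartiteEdgeList] = None
    ppi: Optional[PPINetwork] = None
    validation_report: dict = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_views.ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_sim.ids)

    @property
    def n_proteins(self) -> int:
        return len(self.ppi.protein_ids) if self.ppi is not None else 0

    @property
    def has_protein_branch(self) -> bool:
        return self.ppi is not None

    @property
    def protein_ids(self) -> list[str]:
        return self.ppi.protein_ids if self.ppi is not None else []

    def drug_protein_adjacency(self) -> np.ndarray:
        """Dense M x P binary drug-protein adjacency."""
        return _edge_list_to_dense(
            self.drug_protein.edges, self.drug_views.ids, self.protein_ids
        )

    def disease_protein_adjacency(self) -> np.ndarray:
        return _edge_list_to_dense(
            self.disease_protein.edges, self.disease_sim.ids, self.protein_ids
        )

    def ppi_adjacency(self) -> np.ndarray:
        """Dense symmetric P x P adjacency, zero diagonal."""
        p = {pid: i for i, pid in enumerate(self.protein_ids)}
        adj = np.zeros((len(p), len(p)), dtype=np.int8)
        for a, b in self.ppi.edges:
            adj[p[a], p[b]] = 1
            adj[p[b], p[a]] = 1
        return adj


def _edge_list_to_dense(edges, row_ids, col_ids) -> np.ndarray:
    ri = {x: i for i, x in enumerate(row_ids)}
    ci = {x: i for i, x in enumerate(col_ids)}
    adj = np.zeros((len(ri), len(ci)), dtype=np.int8)
    for a, b in edges:
        adj[ri[a], ci[b]] = 1
    return adj


# -- loaders ------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps load->write->load bit-identical
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def load_similarity_matrix(path) -> SimilarityView:
    """Load a square similarity matrix with id header row and column.

    Symmetrizes asymmetries up to 1e-6 as (P + P.T)/2, forces the
    diagonal to 1, and clips stray values into [0,1] (warning if the
    clip exceeds 1e-6).  Larger asymmetry or out-of-range values are
    errors — they indicate a corrupt file, not numerical noise.
    """
    df = _read_delimited(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square, got {df.shape}")
    mat = df.to_numpy(dtype=np.float64)
    if np.isnan(mat).any():
        raise ValueError(f"{path}: NaN entries in similarity matrix")
    asym = np.abs(mat - mat.T).max()
    if asym > _ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.2e} exceeds tolerance {_ASYMMETRY_TOL}")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    overshoot = max(mat.max() - 1.0, -mat.min(), 0.0)
    if overshoot > _CLIP_TOL:
        raise ValueError(f"{path}: values outside [0,1] by {overshoot:.3g}")
    if overshoot > 0:
        warnings.warn(f"{path}: clipped values into [0,1] by {overshoot:.2e}")
    mat = np.clip(mat, 0.0, 1.0)
    return SimilarityView(ids=[str(i) for i in df.index], matrix=mat)


def load_edge_list(path, source_domain: str, target_domain: str) -> BipartiteEdgeList:
    """Load a two/three-column edge list; a weight column is ignored."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty edge list")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs >= 2 columns")
    pairs = list(dict.fromkeys(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    ))
    logger.info("%s: %d unique %s-%s edges", path, len(pairs), source_domain, target_domain)
    return BipartiteEdgeList(source_domain, target_domain, pairs)


def load_association_matrix(path) -> AssociationMatrix:
    df = _read_delimited(path)
    return AssociationMatrix(
        drug_ids=[str(i) for i in df.index],
        disease_ids=[str(c) for c in df.columns],
        matrix=df.to_numpy(),
    )


# -- writers (round-trip support for the simulate workflow) -------------

def write_similarity_matrix(view: SimilarityView, path) -> None:
    pd.DataFrame(view.matrix, index=view.ids, columns=view.ids).to_csv(path, sep="\t")


def write_association_matrix(assoc: AssociationMatrix, path) -> None:
    pd.DataFrame(
        assoc.matrix, index=assoc.drug_ids, columns=assoc.disease_ids
    ).to_csv(path, sep="\t")


def write_edge_list(edges: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# -- assembly -----------------------------------------------------------

def assemble_network(
    drug_views: MultiViewSimilaritySet,
    disease_sim: SimilarityView,
    assoc: AssociationMatrix,
    drug_protein: Optional[BipartiteEdgeList] = None,
    disease_protein: Optional[BipartiteEdgeList] = None,
    ppi: Optional[PPINetwork] = None,
) -> HeteroNetwork:
    """Validate id consistency across components and build the network.

    The id registry per domain is the ordering of the first-loaded
    component (drug views for drugs, the similarity matrix for diseases,
    the PPI network for proteins); the association matrix and edge lists
    are re-indexed to it.  Entities with no edges are kept but counted
    in the validation report.
    """
    protein_parts = (drug_protein, disease_protein, ppi)
    if any(p is not None for p in protein_parts) and not all(
        p is not None for p in protein_parts
    ):
        raise ValueError("protein components must be all present or all absent")

    for v in drug_views.views:
        v.validate()
    disease_sim.validate()

    if set(assoc.drug_ids) != set(drug_views.ids):
        raise ValueError("association drug ids do not match similarity drug ids")
    if set(assoc.disease_ids) != set(disease_sim.ids):
        raise ValueError("association disease ids do not match disease similarity ids")
    if assoc.drug_ids != drug_views.ids or assoc.disease_ids != disease_sim.ids:
        ridx = [assoc.drug_ids.index(i) for i in drug_views.ids]
        cidx = [assoc.disease_ids.index(i) for i in disease_sim.ids]
        assoc = AssociationMatrix(
            drug_ids=list(drug_views.ids),
            disease_ids=list(disease_sim.ids),
            matrix=assoc.matrix[np.ix_(ridx, cidx)],
        )
    if assoc.n_positive < 1:
        raise ValueError("association matrix has no positive entries")

    report: dict = {
        "n_drugs": len(drug_views.ids),
        "n_diseases": len(disease_sim.ids),
        "n_views": len(drug_views),
        "n_associations": assoc.n_positive,
        "sparsity": compute_sparsity(assoc),
        "warnings": [],
    }

    if ppi is not None:
        protein_set = set(ppi.protein_ids)
        drug_set, disease_set = set(drug_views.ids), set(disease_sim.ids)
        for name, el, src_set in (
            ("drug_protein", drug_protein, drug_set),
            ("disease_protein", disease_protein, disease_set),
        ):
            for a, b in el.edges:
                if a not in src_set:
                    raise ValueError(f"{name}: unknown source id {a!r}")
                if b not in protein_set:
                    raise ValueError(f"{name}: unknown protein id {b!r}")
        dp_drugs = {a for a, _ in drug_protein.edges}
        dp_dis = {a for a, _ in disease_protein.edges}
        # §-style preparation filters are a data concern; just report counts
        few_target_drugs = sum(
            1 for d in drug_views.ids
            if sum(1 for a, _ in drug_protein.edges if a == d) < 2
        )
        report.update(
            n_proteins=len(ppi.protein_ids),
            n_drug_protein_edges=len(drug_protein.edges),
            n_disease_protein_edges=len(disease_protein.edges),
            n_ppi_edges=len(ppi.edges),
            drugs_without_protein=len(drug_set - dp_drugs),
            diseases_without_protein=len(disease_set - dp_dis),
            drugs_with_fewer_than_2_targets=few_target_drugs,
        )

    zero_deg_drugs = int((assoc.matrix.sum(axis=1) == 0).sum())
    zero_deg_dis = int((assoc.matrix.sum(axis=0) == 0).sum())
    if zero_deg_drugs:
        report["warnings"].append(f"{zero_deg_drugs} drugs with no associations")
    if zero_deg_dis:
        report["warnings"].append(f"{zero_deg_dis} diseases with no associations")

    return HeteroNetwork(
        drug_views=drug_views,
        disease_sim=disease_sim,
        assoc=assoc,
        drug_protein=drug_protein,
        disease_protein=disease_protein,
        ppi=ppi,
        validation_report=report,
    )


def compute_sparsity(assoc: AssociationMatrix) -> float:
    """Known associations divided by all possible drug-disease pairs."""
    m, n = assoc.matrix.shape
    return assoc.n_positive / (m * n)


def format_sparsity(value: float, decimals: int = 4) -> str:
    """Display rounding (half-up, as printed in dataset tables)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def write_validation_report(network: HeteroNetwork, path) -> None:
    Path(path).write_text(json.dumps(network.validation_report, indent=2))
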