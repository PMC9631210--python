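"""Multi-source similarity networks for lncRNAs and diseases.

Builds the four similarity networks that feed the node encoder:

* disease semantic similarity (DS) from decay-weighted ancestor
  contributions on the disease ontology DAG (Wang-style measure),
* lncRNA functional similarity (FS) by best-match-average semantic
  similarity of the associated-disease sets,
* Gaussian interaction-profile (GIP) kernels GD / GL over the binary
  association profiles,
* the integrated networks DS(I) / FS(I) and the block-anti-diagonal
  heterogeneous feature matrix X whose rows are raw node features.

Node ordering is diseases-first, then lncRNAs, throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "HeterogeneousFeatureMatrix",
    "OntologyError",
    "build_disease_dag",
    "semantic_value",
    "disease_semantic_similarity",
    "semantic_similarity_from_edges",
    "lncrna_functional_similarity",
    "gaussian_kernel",
    "gaussian_similarity",
    "integrate_disease_similarity",
    "integrate_lncrna_similarity",
    "assemble_feature_matrix",
]

DEFAULT_GAMMA = 0.5  # semantic-contribution decay per ontology generation

SIMILARITY_KINDS = ("semantic", "functional", "gaussian", "integrated")


class OntologyError(ValueError):
    """Raised for malformed ontologies (cycles, unknown identifiers)."""


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary lncRNA x disease association matrix with identifier registries."""

    values: np.ndarray
    lncrna_ids: tuple
    disease_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be binary")
        if v.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError("matrix shape does not match identifier registries")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("need at least one lncRNA and one disease")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))

    @property
    def n_lncrnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    def positives(self) -> list:
        """Known associations as (lncrna_index, disease_index) pairs."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease plus all its ontology ancestors, with decayed contributions.

    ``contributions[t]`` is the semantic contribution of node ``t`` to the
    query disease: 1 for the disease itself, and ``gamma`` times the best
    contribution among ``t``'s children inside the DAG otherwise.
    """

    disease_id: str
    nodes: frozenset
    edges: tuple  # (child, parent) pairs restricted to the DAG
    contributions: Mapping[str, float]
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        if self.disease_id not in self.nodes:
            raise ValueError("query disease must be a DAG node")
        if abs(self.contributions[self.disease_id] - 1.0) > 1e-12:
            raise ValueError("the query disease must have contribution 1")
        if any(not (0.0 < c <= 1.0) for c in self.contributions.values()):
            raise ValueError("contributions must lie in (0, 1]")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered identifier set."""

    values: np.ndarray
    ids: tuple
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("similarity matrix must be square over its ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if self.kind == "integrated":
            if (v < -1e-12).any():
                raise ValueError("integrated similarity must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    def index_of(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown identifier {node_id!r}") from None


@dataclass(frozen=True)
class HeterogeneousFeatureMatrix:
    """Block-anti-diagonal feature matrix X = [[0, DS(I)], [FS(I), 0]].

    Rows (and the feature coordinates of each row) are ordered
    diseases-first then lncRNAs; row i is node i's raw feature vector.
    """

    values: np.ndarray
    disease_ids: tuple
    lncrna_ids: tuple

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Disease semantic similarity (ontology DAG)
# ---------------------------------------------------------------------------

def _parents_map(ontology_edges: Iterable) -> dict:
    parents: dict = {}
    for child, parent in ontology_edges:
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return parents


def build_disease_dag(disease: str, ontology_edges: Iterable,
                      gamma: float = DEFAULT_GAMMA) -> DiseaseDAG:
    """Build the rooted ancestor DAG of ``disease`` with decayed contributions.

    The contribution of the disease itself is 1; every ancestor ``t`` gets
    ``gamma`` times the maximum contribution among ``t``'s children inside
    the DAG, i.e. gamma**d for an ancestor whose closest descent path from
    the query has d edges.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must lie in (0, 1)")
    parents = _parents_map(ontology_edges)
    if disease not in parents:
        raise KeyError(f"disease {disease!r} not found in ontology")

    # collect the disease and all ancestors, detecting cycles on the way up
    nodes: set = set()
    order: list = []  # BFS layers; used only for dedup
    frontier = [disease]
    depth_guard = 0
    while frontier:
        depth_guard += 1
        if depth_guard > len(parents) + 1:
            raise OntologyError("cycle detected among ancestors")
        nxt = []
        for n in frontier:
            if n in nodes:
                continue
            nodes.add(n)
            order.append(n)
            nxt.extend(parents.get(n, ()))
        frontier = nxt

    dag_edges = tuple((c, p) for c, ps in parents.items() if c in nodes
                      for p in ps if p in nodes)
    children_in_dag: dict = {n: [] for n in nodes}
    for c, p in dag_edges:
        children_in_dag[p].append(c)

    contributions: dict = {}

    def contrib(t: str, trail: frozenset) -> float:
        if t in trail:
            raise OntologyError("cycle detected among ancestors")
        if t in contributions:
            return contributions[t]
        if t == disease:
            val = 1.0
        else:
            kids = children_in_dag[t]
            if not kids:
                # unreachable from the query disease; drop from the DAG
                return 0.0
            val = gamma * max(contrib(c, trail | {t}) for c in kids)
        contributions[t] = val
        return val

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(nodes) + 100))
    try:
        for n in nodes:
            contrib(n, frozenset())
    finally:
        sys.setrecursionlimit(old)
    contributions = {k: v for k, v in contributions.items() if v > 0.0}
    kept = frozenset(contributions)
    dag_edges = tuple((c, p) for c, p in dag_edges if c in kept and p in kept)
    return DiseaseDAG(disease_id=disease, nodes=kept, edges=dag_edges,
                      contributions=contributions, gamma=gamma)


def semantic_value(dag: DiseaseDAG) -> float:
    """Total semantic value: the sum of all contributions in the DAG."""
    if not dag.contributions:
        raise ValueError("DAG has no contributions")
    return float(sum(dag.contributions.values()))


def disease_semantic_similarity(dags: Sequence[DiseaseDAG]) -> SimilarityMatrix:
    """Pairwise semantic similarity from shared-ancestor contributions.

    DS(di, dj) = sum over shared DAG nodes m of (D_di(m) + D_dj(m)),
    divided by (S(di) + S(dj)).  The diagonal is exactly 1.
    """
    gammas = {d.gamma for d in dags}
    if len(gammas) > 1:
        raise ValueError("all DAGs must use the same gamma")
    n = len(dags)
    ids = tuple(d.disease_id for d in dags)
    sem = [semantic_value(d) for d in dags]
    out = np.eye(n)
    for i in range(n):
        ci = dags[i].contributions
        for j in range(i + 1, n):
            cj = dags[j].contributions
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[m] + cj[m] for m in shared)
                out[i, j] = out[j, i] = num / (sem[i] + sem[j])
    return SimilarityMatrix(values=out, ids=ids, kind="semantic")


def semantic_similarity_from_edges(disease_ids: Sequence[str],
                                   ontology_edges: Iterable,
                                   gamma: float = DEFAULT_GAMMA) -> SimilarityMatrix:
    """Convenience: build every disease's DAG and the semantic matrix."""
    edges = list(ontology_edges)
    dags = [build_disease_dag(d, edges, gamma) for d in disease_ids]
    return disease_semantic_similarity(dags)


# ---------------------------------------------------------------------------
# lncRNA functional similarity (best-match average)
# ---------------------------------------------------------------------------

def lncrna_functional_similarity(assoc: AssociationMatrix,
                                 ds: SimilarityMatrix) -> SimilarityMatrix:
    """Best-match-average functional similarity between lncRNAs.

    For lncRNAs with associated-disease sets D1 (size m) and D2 (size n):
    FS = (sum over D1 of best match in D2 + sum over D2 of best match in D1)
    divided by (m + n).  A lncRNA with no known associations gets an all-zero
    row/column (the GIP kernel fills those via the integration rule).
    """
    if set(assoc.disease_ids) - set(ds.ids):
        raise ValueError("semantic similarity does not cover all diseases")
    col = np.array([ds.index_of(d) for d in assoc.disease_ids])
    D = ds.values[np.ix_(col, col)]
    nl = assoc.n_lncrnas
    sets = [np.nonzero(assoc.values[i])[0] for i in range(nl)]
    empty = [i for i in range(nl) if sets[i].size == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} lncRNA(s) have no known associations; functional "
            "similarity set to 0 for them", stacklevel=2)
    out = np.zeros((nl, nl))
    for i in range(nl):
        if sets[i].size == 0:
            continue
        for j in range(i, nl):
            if sets[j].size == 0:
                continue
            sub = D[np.ix_(sets[i], sets[j])]
            num = sub.max(axis=1).sum() + sub.max(axis=0).sum()
            out[i, j] = out[j, i] = num / (sets[i].size + sets[j].size)
    return SimilarityMatrix(values=out, ids=assoc.lncrna_ids, kind="functional")


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels
# ---------------------------------------------------------------------------

def gaussian_kernel(profiles: np.ndarray, ids: Sequence[str]) -> SimilarityMatrix:
    """GIP kernel over binary interaction profiles (one profile per row).

    The bandwidth is the reciprocal of the mean squared profile norm;
    entries are exp(-bandwidth * ||IP(i) - IP(j)||^2).
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D array (one row per node)")
    if not np.isin(P, (0.0, 1.0)).all():
        raise ValueError("interaction profiles must be binary")
    sq_norms = (P * P).sum(axis=1)
    mean_norm = sq_norms.mean()
    if mean_norm == 0.0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    bandwidth = 1.0 / mean_norm
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    vals = np.exp(-bandwidth * d2)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(values=vals, ids=tuple(ids), kind="gaussian")


def gaussian_similarity(assoc: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """GIP similarity of diseases (columns of A) or lncRNAs (rows of A)."""
    if axis == "disease":
        return gaussian_kernel(assoc.values.T, assoc.disease_ids)
    if axis == "lncrna":
        return gaussian_kernel(assoc.values, assoc.lncrna_ids)
    raise ValueError("axis must be 'disease' or 'lncrna'")


# ---------------------------------------------------------------------------
# Integration and feature assembly
# ---------------------------------------------------------------------------

def _check_aligned(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.ids != b.ids:
        raise ValueError("similarity matrices are not aligned on identifiers")


def integrate_disease_similarity(ds: SimilarityMatrix, gd: SimilarityMatrix,
                                 average: bool = False) -> SimilarityMatrix:
    """Integrated disease similarity: DS+GD where DS is nonzero, else GD.

    The literal sum can exceed 1; set ``average=True`` to use (DS+GD)/2 in
    the nonzero branch instead.
    """
    _check_aligned(ds, gd)
    combined = ds.values + gd.values
    if average:
        combined = combined / 2.0
    vals = np.where(ds.values != 0.0, combined, gd.values)
    return SimilarityMatrix(values=vals, ids=ds.ids, kind="integrated")


def integrate_lncrna_similarity(fs: SimilarityMatrix,
                                gl: SimilarityMatrix) -> SimilarityMatrix:
    """Integrated lncRNA similarity: FS where nonzero, else GL (no sum)."""
    _check_aligned(fs, gl)
    vals = np.where(fs.values != 0.0, fs.values, gl.values)
    return SimilarityMatrix(values=vals, ids=fs.ids, kind="integrated")


def assemble_feature_matrix(ds_i: SimilarityMatrix,
                            fs_i: SimilarityMatrix) -> HeterogeneousFeatureMatrix:
    """Assemble the heterogeneous feature matrix X, diseases-first.

    X = [[0_(nd x nl), DS(I)], [FS(I), 0_(nl x nd)]], shape
    (nd+nl) x (nl+nd); each row is the raw feature vector of one node.
    """
    nd = len(ds_i.ids)
    nl = len(fs_i.ids)
    X = np.zeros((nd + nl, nl + nd))
    X[:nd, nl:] = ds_i.values
    X[nd:, :nl] = fs_i.values
    return HeterogeneousFeatureMatrix(values=X, disease_ids=ds_i.ids,
                                      lncrna_ids=fs_i.ids)
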