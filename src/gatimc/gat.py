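"""Graph-attention node encoder with multiple-operator head aggregation.

Each attention head scores every edge of the heterogeneous graph with a
single-layer network LeakyReLU(a . [W*h_i || W*h_j]), softmax-normalizes
the scores over each neighborhood, and aggregates neighbor features into
h_Ni.  The head output then combines three operators -- a sum branch
LeakyReLU((h_i + h_Ni) W1_sum), a concatenation branch
LeakyReLU([h_i || h_Ni] W1_cat) and their elementwise product -- and the
per-head outputs are concatenated into the final embedding matrix M,
split into a disease block Md and a lncRNA block Ml (diseases first).

``encode`` runs the vectorized autodiff path used in training; the
per-node operations (``attention_scores``, ``normalize_attention``,
``aggregate_neighbors``, ``multi_operator_aggregate``) are plain-numpy
equivalents of one head acting on one node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, concat, glorot_uniform
from .similarity import AssociationMatrix, HeterogeneousFeatureMatrix, SimilarityMatrix

__all__ = [
    "AttentionHeadParams",
    "NodeEmbeddings",
    "NeighborIndex",
    "DEFAULT_LEAKY_SLOPE",
    "init_head_params",
    "build_neighbor_index",
    "attention_scores",
    "normalize_attention",
    "aggregate_neighbors",
    "multi_operator_aggregate",
    "encode_tensor",
    "encode",
]

DEFAULT_LEAKY_SLOPE = 0.2
DEFAULT_N_HEADS = 6
DEFAULT_NEURONS = 16


@dataclass
class AttentionHeadParams:
    """Trainable parameters of one attention head.

    ``W`` scales features elementwise before scoring; ``a_self``/``a_neigh``
    are the two halves of the scoring vector a; ``W1_sum`` (d x k) projects
    the sum branch and ``W1_cat`` (2d x k) the concatenation branch.
    """

    W: Tensor
    a_self: Tensor
    a_neigh: Tensor
    W1_sum: Tensor
    W1_cat: Tensor
    leaky_slope: float = DEFAULT_LEAKY_SLOPE

    def tensors(self) -> list:
        return [self.W, self.a_self, self.a_neigh, self.W1_sum, self.W1_cat]

    def projection_tensors(self) -> list:
        """The weights that carry the L2 penalty."""
        return [self.W1_sum, self.W1_cat]


@dataclass(frozen=True)
class NodeEmbeddings:
    """Encoded node features, diseases-first; columns = heads x neurons."""

    M: np.ndarray
    n_diseases: int
    n_lncrnas: int

    def __post_init__(self):
        if self.M.shape[0] != self.n_diseases + self.n_lncrnas:
            raise ValueError("embedding rows must cover all nodes")

    @property
    def Md(self) -> np.ndarray:
        return self.M[: self.n_diseases]

    @property
    def Ml(self) -> np.ndarray:
        return self.M[self.n_diseases:]


@dataclass(frozen=True)
class NeighborIndex:
    """Symmetric neighbor mask over the heterogeneous graph, with self-loops."""

    mask: np.ndarray  # boolean (N, N)
    n_diseases: int
    n_lncrnas: int

    def __post_init__(self):
        if not self.mask.diagonal().all():
            raise ValueError("every node needs a self-loop")

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self.mask[i])[0]


def init_head_params(rng: np.random.Generator, n_features: int, neurons: int,
                     leaky_slope: float = DEFAULT_LEAKY_SLOPE) -> AttentionHeadParams:
    """Glorot-uniform initialization of one head's parameters."""
    d = n_features
    return AttentionHeadParams(
        W=Tensor(glorot_uniform(rng, (d,))),
        a_self=Tensor(glorot_uniform(rng, (d, 1))),
        a_neigh=Tensor(glorot_uniform(rng, (d, 1))),
        W1_sum=Tensor(glorot_uniform(rng, (d, neurons))),
        W1_cat=Tensor(glorot_uniform(rng, (2 * d, neurons))),
        leaky_slope=leaky_slope,
    )


def build_neighbor_index(assoc: AssociationMatrix, ds_i: SimilarityMatrix,
                         fs_i: SimilarityMatrix) -> NeighborIndex:
    """Adjacency of the heterogeneous graph, diseases-first with self-loops.

    A disease's neighbors are the lncRNAs associated with it plus the
    diseases with nonzero integrated similarity; symmetrically for lncRNAs.
    """
    if assoc.disease_ids != ds_i.ids or assoc.lncrna_ids != fs_i.ids:
        raise ValueError("identifiers are not aligned")
    nd, nl = assoc.n_diseases, assoc.n_lncrnas
    n = nd + nl
    mask = np.zeros((n, n), dtype=bool)
    mask[:nd, :nd] = ds_i.values != 0.0
    mask[nd:, nd:] = fs_i.values != 0.0
    mask[:nd, nd:] = assoc.values.T != 0.0
    mask[nd:, :nd] = assoc.values != 0.0
    mask |= mask.T
    np.fill_diagonal(mask, True)
    return NeighborIndex(mask=mask, n_diseases=nd, n_lncrnas=nl)


# ---------------------------------------------------------------------------
# Per-node reference operations (plain numpy, one head / one node)
# ---------------------------------------------------------------------------

def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def attention_scores(h_i: np.ndarray, h_j: np.ndarray,
                     params: AttentionHeadParams) -> float:
    """Raw attention score e_ij = LeakyReLU(a . [W*h_i || W*h_j])."""
    h_i = np.asarray(h_i, float)
    h_j = np.asarray(h_j, float)
    W = params.W.data
    if h_i.shape != W.shape or h_j.shape != W.shape:
        raise ValueError("feature vectors do not match the scoring weights")
    raw = float((W * h_i) @ params.a_self.data.ravel()
                + (W * h_j) @ params.a_neigh.data.ravel())
    return float(_leaky(np.array(raw), params.leaky_slope))


def normalize_attention(scores: Sequence[float]) -> np.ndarray:
    """Softmax over one neighborhood's raw scores."""
    s = np.asarray(scores, float)
    if s.size == 0:
        raise ValueError("empty neighborhood")
    z = np.exp(s - s.max())
    return z / z.sum()


def aggregate_neighbors(alpha: Sequence[float],
                        neighbor_features: np.ndarray) -> np.ndarray:
    """Convex combination of neighbor feature vectors."""
    a = np.asarray(alpha, float)
    H = np.asarray(neighbor_features, float)
    if a.shape[0] != H.shape[0]:
        raise ValueError("coefficient/neighbor count mismatch")
    return a @ H


def multi_operator_aggregate(h_i: np.ndarray, h_Ni: np.ndarray,
                             params: AttentionHeadParams) -> np.ndarray:
    """Combine sum, concatenation and elementwise-product branches.

    Returns LeakyReLU((h_i+h_Ni) W1_sum) + LeakyReLU([h_i||h_Ni] W1_cat)
    plus the elementwise product of the two branches; length = neurons.
    """
    h_i = np.asarray(h_i, float)
    h_Ni = np.asarray(h_Ni, float)
    slope = params.leaky_slope
    s = _leaky((h_i + h_Ni) @ params.W1_sum.data, slope)
    c = _leaky(np.concatenate([h_i, h_Ni]) @ params.W1_cat.data, slope)
    return s + c + s * c


# ---------------------------------------------------------------------------
# Vectorized autodiff forward pass
# ---------------------------------------------------------------------------

def _head_forward(Xt: Tensor, mask: np.ndarray, hp: AttentionHeadParams,
                  concat_only: bool) -> tuple:
    """One head over all nodes; returns (output Tensor, attention ndarray)."""
    slope = hp.leaky_slope
    Wh = Xt * hp.W  # broadcast elementwise scaling
    s_self = Wh @ hp.a_self  # (N, 1)
    s_neigh = Wh @ hp.a_neigh  # (N, 1)
    E = (s_self + s_neigh.T).leaky_relu(slope)
    # masked row softmax; the shift is a constant so its gradient cancels
    # (max over the full row keeps the masked exp from overflowing too)
    shift = E.data.max(axis=1, keepdims=True)
    Z = (E - shift).exp() * mask.astype(float)
    alpha = Z / Z.sum(axis=1, keepdims=True)
    Hn = alpha @ Xt
    c = (concat([Xt, Hn], axis=1) @ hp.W1_cat).leaky_relu(slope)
    if concat_only:
        return c, alpha.data
    s = ((Xt + Hn) @ hp.W1_sum).leaky_relu(slope)
    return s + c + s * c, alpha.data


def encode_tensor(Xt: Tensor, index: NeighborIndex,
                  heads: Sequence[AttentionHeadParams],
                  concat_only: bool = False) -> tuple:
    """Differentiable forward pass; returns (M Tensor, per-head attention)."""
    if len(heads) < 1:
        raise ValueError("need at least one attention head")
    outs, alphas = [], []
    for hp in heads:
        out, alpha = _head_forward(Xt, index.mask, hp, concat_only)
        outs.append(out)
        alphas.append(alpha)
    M = outs[0] if len(outs) == 1 else concat(outs, axis=1)
    return M, alphas


def encode(X: HeterogeneousFeatureMatrix, index: NeighborIndex,
           heads: Sequence[AttentionHeadParams],
           concat_only: bool = False) -> NodeEmbeddings:
    """Encode all nodes; convenience numpy wrapper around ``encode_tensor``."""
    M, alphas = encode_tensor(Tensor(X.values), index, heads, concat_only)
    for alpha in alphas:
        row_sums = alpha.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise AssertionError("attention coefficients do not sum to 1")
    return NodeEmbeddings(M=M.data, n_diseases=len(X.disease_ids),
                          n_lncrnas=len(X.lncrna_ids))
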