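"""Inductive matrix completion over encoded node features.

The association matrix is reconstructed as ``(Ml @ Pl) @ (Md @ Pd)^T``
where Md / Ml are the encoded disease and lncRNA feature blocks and
Pd / Pl are learned low-rank projections -- the inductive
parameterization whose size depends only on the feature dimension, so
columns (or rows) with no observed associations still receive informative
scores (the cold-start property).  Everything is trained end-to-end with
Adam on the squared-Frobenius reconstruction loss plus an L2 penalty on
the projection weights; reported scores pass through a sigmoid so they
live in [0, 1] (a monotone map, leaving rankings and AUC unchanged).

By default each embedding column is mean-centered over nodes before the
projections: the LeakyReLU head outputs share a large positive offset (a
near rank-1 component of M) that otherwise dominates the bilinear fit and
stalls optimization for hundreds of epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from ._autodiff import Adam, Tensor, glorot_uniform
from .gat import (AttentionHeadParams, NeighborIndex, NodeEmbeddings,
                  build_neighbor_index, encode_tensor, init_head_params)
from .io import RunConfig
from .similarity import (AssociationMatrix, HeterogeneousFeatureMatrix,
                         SimilarityMatrix, assemble_feature_matrix)

__all__ = [
    "ModelParams",
    "ReconstructedMatrix",
    "TrainResult",
    "init_model",
    "reconstruct",
    "loss",
    "train",
    "predict_scores",
    "rank_candidates",
    "params_to_jsonable",
    "params_from_jsonable",
]


@dataclass
class ModelParams:
    """All trainable weights plus the hyperparameters that shaped them."""

    heads: list  # AttentionHeadParams; empty for the plain_mc variant
    Pd: Optional[Tensor]  # (n_heads*neurons, rank)
    Pl: Optional[Tensor]
    U: Optional[Tensor] = None  # direct factors, plain_mc only (nl, rank)
    V: Optional[Tensor] = None  # (nd, rank)
    config: Optional[RunConfig] = None

    def trainable(self) -> list:
        out = []
        for hp in self.heads:
            out.extend(hp.tensors())
        out.extend(t for t in (self.Pd, self.Pl, self.U, self.V) if t is not None)
        return out

    def regularized(self) -> list:
        """Projection weights carrying the L2 penalty."""
        out = []
        for hp in self.heads:
            out.extend(hp.projection_tensors())
        out.extend(t for t in (self.Pd, self.Pl, self.U, self.V) if t is not None)
        return out


@dataclass(frozen=True)
class ReconstructedMatrix:
    """Reconstructed association matrix, lncRNA x disease.

    ``scores`` are the sigmoid-bounded values in [0, 1] used for ranking;
    ``logits`` keeps the raw (pre-sigmoid) reconstruction that the
    Frobenius loss is computed on.
    """

    scores: np.ndarray
    lncrna_ids: tuple
    disease_ids: tuple
    logits: Optional[np.ndarray] = None

    def __post_init__(self):
        if not np.isfinite(self.scores).all():
            raise ValueError("reconstruction contains non-finite scores")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("scores must lie in [0, 1]")
        if self.logits is None:
            with np.errstate(divide="ignore"):
                object.__setattr__(self, "logits",
                                   np.log(self.scores / (1.0 - self.scores)))


@dataclass
class TrainResult:
    params: ModelParams
    losses: list
    recon: ReconstructedMatrix


def init_model(rng: np.random.Generator, n_features: int, nl: int, nd: int,
               config: RunConfig) -> ModelParams:
    """Glorot-uniform initialization of every trainable tensor."""
    r = config.effective_rank
    s = config.proj_init_scale
    if config.variant == "plain_mc":
        return ModelParams(
            heads=[],
            Pd=None, Pl=None,
            U=Tensor(s * glorot_uniform(rng, (nl, r))),
            V=Tensor(s * glorot_uniform(rng, (nd, r))),
            config=config,
        )
    heads = [init_head_params(rng, n_features, config.neurons, config.leaky_slope)
             for _ in range(config.n_heads)]
    emb_dim = config.n_heads * config.neurons
    return ModelParams(
        heads=heads,
        Pd=Tensor(s * glorot_uniform(rng, (emb_dim, r))),
        Pl=Tensor(s * glorot_uniform(rng, (emb_dim, r))),
        config=config,
    )


def reconstruct(embeddings: NodeEmbeddings, params: ModelParams,
                lncrna_ids: Sequence[str], disease_ids: Sequence[str],
                center: bool = True) -> ReconstructedMatrix:
    """Scores sigmoid((Ml Pl)(Md Pd)^T) from fixed embeddings.

    ``center`` mean-centers embedding columns over nodes first (the
    package default during training).
    """
    if not np.isfinite(embeddings.M).all():
        raise ValueError("embeddings contain non-finite values")
    Md, Ml = embeddings.Md, embeddings.Ml
    if center:
        Md = Md - Md.mean(axis=0, keepdims=True)
        Ml = Ml - Ml.mean(axis=0, keepdims=True)
    logits = (Ml @ params.Pl.data) @ (Md @ params.Pd.data).T
    return ReconstructedMatrix(scores=expit(logits), logits=logits,
                               lncrna_ids=tuple(lncrna_ids),
                               disease_ids=tuple(disease_ids))


def loss(assoc_train: AssociationMatrix, recon: ReconstructedMatrix,
         params: ModelParams, lam: float = 1.0) -> float:
    """Squared Frobenius reconstruction error plus L2 weight penalty.

    The error is computed on the raw (pre-sigmoid) reconstruction --
    the quantity the optimizer actually minimizes.
    """
    if assoc_train.values.shape != recon.scores.shape:
        raise ValueError("association and reconstruction shapes differ")
    sse = float(((assoc_train.values - recon.logits) ** 2).sum())
    reg = sum(float((t.data ** 2).sum()) for t in params.regularized())
    return sse + lam * reg


def _forward(Xt: Tensor, index: NeighborIndex, params: ModelParams,
             nd: int, config: RunConfig):
    """Differentiable raw reconstruction (nl x nd) and per-head attention."""
    if config.variant == "plain_mc":
        return params.U @ params.V.T, []
    M, alphas = encode_tensor(Xt, index, params.heads,
                              concat_only=(config.variant == "plain_gat"))
    Md = M[:nd]
    Ml = M[nd:]
    if config.center_embeddings:
        n_l = Ml.shape[0]
        Md = Md - Md.sum(axis=0, keepdims=True) * (1.0 / nd)
        Ml = Ml - Ml.sum(axis=0, keepdims=True) * (1.0 / n_l)
    logits = (Ml @ params.Pl) @ (Md @ params.Pd).T
    return logits, alphas


def _loss_tensor(A: np.ndarray, logits: Tensor, params: ModelParams,
                 lam: float) -> Tensor:
    diff = Tensor(A) - logits
    total = (diff * diff).sum()
    for t in params.regularized():
        total = total + lam * (t * t).sum()
    return total


def train(assoc_train: AssociationMatrix, ds_i: SimilarityMatrix,
          fs_i: SimilarityMatrix, config: RunConfig,
          rng: Optional[np.random.Generator] = None) -> TrainResult:
    """Fit the encoder and the IMC projections end-to-end with Adam.

    Test positives must already be zeroed in ``assoc_train``; every matrix
    entry participates in the loss (unknown pairs act as weak negatives).
    Deterministic given the generator state.
    """
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nd, nl = assoc_train.n_diseases, assoc_train.n_lncrnas
    X = assemble_feature_matrix(ds_i, fs_i)
    index = build_neighbor_index(assoc_train, ds_i, fs_i)
    Xt = Tensor(X.values)
    params = init_model(rng, X.values.shape[1], nl, nd, config)
    opt = Adam(params.trainable(), lr=config.lr,
               weight_decay=config.weight_decay)
    A = assoc_train.values
    losses = []
    for epoch in range(config.epochs):
        logits, alphas = _forward(Xt, index, params, nd, config)
        total = _loss_tensor(A, logits, params, config.lam)
        if not np.isfinite(total.data):
            raise RuntimeError(f"training diverged at epoch {epoch}: "
                               f"loss={float(total.data)}")
        total.backward()
        opt.step()
        losses.append(float(total.data))
    final_logits, _ = _forward(Xt, index, params, nd, config)
    recon = ReconstructedMatrix(scores=expit(final_logits.data),
                                logits=final_logits.data,
                                lncrna_ids=assoc_train.lncrna_ids,
                                disease_ids=assoc_train.disease_ids)
    return TrainResult(params=params, losses=losses, recon=recon)


def predict_scores(assoc_train: AssociationMatrix, ds_i: SimilarityMatrix,
                   fs_i: SimilarityMatrix, params: ModelParams,
                   config: Optional[RunConfig] = None) -> ReconstructedMatrix:
    """Forward pass with fixed parameters (no training)."""
    if config is None:
        config = params.config or RunConfig()
    nd = assoc_train.n_diseases
    X = assemble_feature_matrix(ds_i, fs_i)
    index = build_neighbor_index(assoc_train, ds_i, fs_i)
    logits, _ = _forward(Tensor(X.values), index, params, nd, config)
    return ReconstructedMatrix(scores=expit(logits.data), logits=logits.data,
                               lncrna_ids=assoc_train.lncrna_ids,
                               disease_ids=assoc_train.disease_ids)


def params_to_jsonable(params: ModelParams) -> dict:
    """Serialize all trainable weights to a JSON-friendly dict."""
    def arr(t):
        return None if t is None else t.data.tolist()

    return {
        "heads": [{"W": arr(hp.W), "a_self": arr(hp.a_self),
                   "a_neigh": arr(hp.a_neigh), "W1_sum": arr(hp.W1_sum),
                   "W1_cat": arr(hp.W1_cat), "leaky_slope": hp.leaky_slope}
                  for hp in params.heads],
        "Pd": arr(params.Pd), "Pl": arr(params.Pl),
        "U": arr(params.U), "V": arr(params.V),
        "config": params.config.to_dict() if params.config else None,
    }


def params_from_jsonable(d: dict) -> ModelParams:
    """Inverse of :func:`params_to_jsonable`."""
    def ten(x):
        return None if x is None else Tensor(np.asarray(x, dtype=float))

    heads = [AttentionHeadParams(W=ten(h["W"]), a_self=ten(h["a_self"]),
                                 a_neigh=ten(h["a_neigh"]),
                                 W1_sum=ten(h["W1_sum"]),
                                 W1_cat=ten(h["W1_cat"]),
                                 leaky_slope=h["leaky_slope"])
             for h in d["heads"]]
    config = RunConfig.from_dict(d["config"]) if d.get("config") else None
    return ModelParams(heads=heads, Pd=ten(d["Pd"]), Pl=ten(d["Pl"]),
                       U=ten(d["U"]), V=ten(d["V"]), config=config)


def rank_candidates(recon: ReconstructedMatrix, disease_id: str,
                    known: Optional[AssociationMatrix] = None,
                    exclude_known: bool = False,
                    top: Optional[int] = None) -> list:
    """Candidate lncRNAs for one disease, best first.

    Sorted by descending score with ties broken lexicographically by
    lncRNA identifier; known positives are dropped when ``exclude_known``.
    """
    try:
        j = recon.disease_ids.index(disease_id)
    except ValueError:
        raise KeyError(f"unknown disease {disease_id!r}") from None
    excluded: set = set()
    if exclude_known:
        if known is None:
            raise ValueError("exclude_known requires the known associations")
        kj = known.disease_ids.index(disease_id)
        excluded = {known.lncrna_ids[i]
                    for i in np.nonzero(known.values[:, kj])[0]}
    ranked = [(lid, float(recon.scores[i, j]))
              for i, lid in enumerate(recon.lncrna_ids) if lid not in excluded]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked if top is None else ranked[:top]
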