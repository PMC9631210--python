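"""Cross-validated evaluation: fold construction, AUC/AUPR, ablations.

Known associations are partitioned into k folds; each fold's positives
are masked from training and scored against an equal-sized sample of
unknown pairs (drawn uniformly without replacement, re-sampled per
repeat).  Similarity networks that depend on the association matrix (the
functional similarity and both GIP kernels) are recomputed from the
training matrix of every fold so no test information leaks into the
features.  AUC uses the Mann-Whitney ties-as-half convention; AUPR uses
the step-wise (non-interpolated) precision-recall area.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from .imc import init_model, predict_scores, train
from .io import RunConfig
from .similarity import (AssociationMatrix, SimilarityMatrix,
                         assemble_feature_matrix, gaussian_similarity,
                         integrate_disease_similarity,
                         integrate_lncrna_similarity,
                         lncrna_functional_similarity)

__all__ = [
    "FoldSplit",
    "CVResult",
    "make_folds",
    "roc_auc",
    "pr_auc",
    "fold_similarities",
    "run_cv",
    "run_ablation",
]

ABLATION_VARIANTS = ("full", "no_gaussian", "plain_gat", "plain_mc")


@dataclass(frozen=True)
class FoldSplit:
    """One fold: masked test positives plus an equal-sized negative sample."""

    fold_id: int
    train_positive: tuple
    test_positive: tuple
    test_negative: tuple


@dataclass
class CVResult:
    """Per-fold metrics and their mean over repeats x folds."""

    auc: float
    aupr: float
    fold_aucs: list
    fold_auprs: list
    folds: int
    repeats: int
    curves: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "folds": self.folds,
            "repeats": self.repeats,
            "fold_aucs": self.fold_aucs,
            "fold_auprs": self.fold_auprs,
        }


def make_folds(assoc: AssociationMatrix, k: int = 5,
               seed: int | Sequence[int] = 0) -> list:
    """Partition positives into k folds with matched negative samples.

    Negatives are unknown pairs drawn uniformly without replacement, one
    disjoint sample per fold, the same count as that fold's positives.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    pos = assoc.positives()
    if len(pos) < k:
        raise ValueError("fewer positives than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    groups = np.array_split(order, k)
    zero_rows, zero_cols = np.nonzero(assoc.values == 0)
    unknown = list(zip(zero_rows.tolist(), zero_cols.tolist()))
    if len(unknown) < max(len(g) for g in groups):
        raise ValueError("not enough unknown pairs to sample negatives")
    pos_set = set(pos)
    neg_order = rng.permutation(len(unknown))
    folds = []
    cursor = 0
    for fid, g in enumerate(groups):
        test_pos = tuple(pos[i] for i in g.tolist())
        n_neg = len(test_pos)
        take = neg_order[cursor: cursor + n_neg]
        if take.size < n_neg:
            raise ValueError("not enough unknown pairs to sample negatives")
        cursor += n_neg
        test_neg = tuple(unknown[i] for i in take.tolist())
        assert not (set(test_neg) & pos_set)
        train_pos = tuple(p for i, p in enumerate(pos) if i not in set(g.tolist()))
        folds.append(FoldSplit(fold_id=fid, train_positive=train_pos,
                               test_positive=test_pos, test_negative=test_neg))
    return folds


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties = 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if (y == 1).sum() == 0:
        raise ValueError("pr_auc needs at least one positive")
    precision, recall, _ = precision_recall_curve(y, s)
    # arrays run from recall 1 down to 0; sum P_n * (R_n - R_{n-1})
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def _align_semantic(ds: SimilarityMatrix, ids: Sequence[str]) -> SimilarityMatrix:
    if ds.ids == tuple(ids):
        return ds
    idx = [ds.index_of(i) for i in ids]
    return SimilarityMatrix(values=ds.values[np.ix_(idx, idx)],
                            ids=tuple(ids), kind=ds.kind)


def fold_similarities(assoc_train: AssociationMatrix, ds: SimilarityMatrix,
                      config: RunConfig):
    """Integrated similarity pair (DS(I), FS(I)) from a training matrix."""
    ds = _align_semantic(ds, assoc_train.disease_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fold masking creates empty rows
        fs = lncrna_functional_similarity(assoc_train, ds)
    if config.variant == "no_gaussian":
        gd = SimilarityMatrix(np.zeros_like(ds.values), ds.ids, "gaussian")
        gl = SimilarityMatrix(np.zeros_like(fs.values), fs.ids, "gaussian")
    else:
        gd = gaussian_similarity(assoc_train, "disease")
        gl = gaussian_similarity(assoc_train, "lncrna")
    ds_i = integrate_disease_similarity(ds, gd, average=config.average_integration)
    fs_i = integrate_lncrna_similarity(fs, gl)
    return ds_i, fs_i


def _masked_train(assoc: AssociationMatrix, test_positive) -> AssociationMatrix:
    values = assoc.values.copy()
    for i, j in test_positive:
        values[i, j] = 0.0
    return AssociationMatrix(values=values, lncrna_ids=assoc.lncrna_ids,
                             disease_ids=assoc.disease_ids)


def run_cv(assoc: AssociationMatrix, ds: SimilarityMatrix, config: RunConfig,
           repeats: Optional[int] = None, train_model: bool = True,
           keep_curves: bool = False) -> CVResult:
    """k-fold cross-validation averaged over repeats.

    ``train_model=False`` scores with freshly initialized, untrained
    parameters -- the frozen-random-projection baseline.
    """
    repeats = config.repeats if repeats is None else repeats
    fold_aucs, fold_auprs, curves = [], [], []
    for rep in range(repeats):
        folds = make_folds(assoc, config.folds, seed=[config.seed, 11, rep])
        for fold in folds:
            assoc_train = _masked_train(assoc, fold.test_positive)
            ds_i, fs_i = fold_similarities(assoc_train, ds, config)
            rng = np.random.default_rng([config.seed, 13, rep, fold.fold_id])
            if train_model:
                result = train(assoc_train, ds_i, fs_i, config, rng=rng)
                recon = result.recon
            else:
                X = assemble_feature_matrix(ds_i, fs_i)
                params = init_model(rng, X.values.shape[1],
                                    assoc.n_lncrnas, assoc.n_diseases, config)
                recon = predict_scores(assoc_train, ds_i, fs_i, params,
                                       config=config)
            pairs = list(fold.test_positive) + list(fold.test_negative)
            scores = np.array([recon.scores[i, j] for i, j in pairs])
            labels = np.array([1] * len(fold.test_positive)
                              + [0] * len(fold.test_negative))
            fold_aucs.append(roc_auc(scores, labels))
            fold_auprs.append(pr_auc(scores, labels))
            if keep_curves:
                fpr, tpr, _ = roc_curve(labels, scores)
                prec, rec, _ = precision_recall_curve(labels, scores)
                curves.append({"repeat": rep, "fold": fold.fold_id,
                               "fpr": fpr, "tpr": tpr,
                               "precision": prec, "recall": rec})
    return CVResult(auc=float(np.mean(fold_aucs)),
                    aupr=float(np.mean(fold_auprs)),
                    fold_aucs=fold_aucs, fold_auprs=fold_auprs,
                    folds=config.folds, repeats=repeats, curves=curves)


def run_ablation(assoc: AssociationMatrix, ds: SimilarityMatrix,
                 config: RunConfig, variant: str,
                 repeats: Optional[int] = None) -> CVResult:
    """Cross-validate one ablation variant under the otherwise-same protocol.

    ``no_gaussian`` drops the GIP kernels before integration, ``plain_gat``
    keeps only the concatenation branch of the head combiner, and
    ``plain_mc`` learns the factor matrices directly without node features.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    cfg = dataclasses.replace(config, variant=variant)
    return run_cv(assoc, ds, cfg, repeats=repeats)
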