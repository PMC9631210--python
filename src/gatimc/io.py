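"""File formats, run configuration and manifests.

All data files are tab-delimited UTF-8: association lists are two-column
(lncrna_id, disease_id), ontologies are child->parent edge lists with
``#`` comments, and matrices are dense TSVs with an identifier header row
and first column.  Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .similarity import AssociationMatrix, SimilarityMatrix

__all__ = [
    "RunConfig",
    "read_associations",
    "write_associations",
    "read_ontology",
    "read_matrix",
    "write_matrix",
    "write_manifest",
]

logger = logging.getLogger("gatimc")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline.

    Defaults follow the model-selection study: 6 attention heads, 16
    neurons per head, weight decay 5e-2, regularization weight 1, decay
    gamma 0.5 for semantic contributions, 5-fold cross-validation repeated
    10 times.  Learning rate, epoch count and projection rank are free
    choices (rank ``None`` means heads x neurons).

    ``center_embeddings`` mean-centers each embedding column over nodes
    before the completion projections (removes the shared positive offset
    of the LeakyReLU head outputs, which otherwise dominates the bilinear
    fit); ``proj_init_scale`` shrinks the initial projections so the
    reconstruction starts near zero.
    """

    n_heads: int = 6
    neurons: int = 16
    leaky_slope: float = 0.2
    weight_decay: float = 5e-2
    lam: float = 1.0
    lr: float = 0.01
    epochs: int = 200
    rank: Optional[int] = None
    gamma: float = 0.5
    folds: int = 5
    repeats: int = 10
    variant: str = "full"
    average_integration: bool = False
    center_embeddings: bool = True
    proj_init_scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("full", "no_gaussian", "plain_gat", "plain_mc"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.n_heads < 1 or self.neurons < 1 or self.folds < 2:
            raise ValueError("invalid configuration")

    @property
    def effective_rank(self) -> int:
        return self.rank if self.rank is not None else self.n_heads * self.neurons

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_associations(path) -> AssociationMatrix:
    """Read a two-column (lncrna_id, disease_id) TSV into a binary matrix.

    Identifier registries follow first appearance; duplicated pairs are
    collapsed to a single 1 with a warning.
    """
    lncrnas: list = []
    diseases: list = []
    l_index: dict = {}
    d_index: dict = {}
    pairs: list = []
    seen = set()
    dupes = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated "
                                 f"identifiers, got {line!r}")
            lnc, dis = parts
            if lnc not in l_index:
                l_index[lnc] = len(lncrnas)
                lncrnas.append(lnc)
            if dis not in d_index:
                d_index[dis] = len(diseases)
                diseases.append(dis)
            key = (l_index[lnc], d_index[dis])
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            pairs.append(key)
    if not pairs:
        raise ValueError(f"{path}: no association pairs found")
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicated pair(s) collapsed",
                      stacklevel=2)
    values = np.zeros((len(lncrnas), len(diseases)))
    for i, j in pairs:
        values[i, j] = 1.0
    return AssociationMatrix(values=values, lncrna_ids=tuple(lncrnas),
                             disease_ids=tuple(diseases))


def write_associations(assoc: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in assoc.positives():
            fh.write(f"{assoc.lncrna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_ontology(path) -> list:
    """Read a child->parent edge list TSV (``#`` comments allowed)."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected child<TAB>parent")
            edges.append((parts[0], parts[1]))
    return edges


def write_ontology(edges, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def write_matrix(values: np.ndarray, row_ids, col_ids, path) -> None:
    """Write a labeled dense matrix TSV at full float precision."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("refusing to write non-finite matrix entries")
    df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format=None, index_label="id")


def read_matrix(path, expected_row_ids=None, expected_col_ids=None):
    """Read a labeled dense matrix TSV; returns (values, row_ids, col_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    row_ids = tuple(str(i) for i in df.index)
    col_ids = tuple(str(c) for c in df.columns)
    if expected_row_ids is not None and tuple(expected_row_ids) != row_ids:
        raise ValueError(f"{path}: row identifiers do not match the expected registry")
    if expected_col_ids is not None and tuple(expected_col_ids) != col_ids:
        raise ValueError(f"{path}: column identifiers do not match the expected registry")
    return df.to_numpy(dtype=float), row_ids, col_ids


def read_similarity(path, kind: str) -> SimilarityMatrix:
    values, row_ids, col_ids = read_matrix(path)
    if row_ids != col_ids:
        raise ValueError(f"{path}: similarity matrix must have matching row/column ids")
    return SimilarityMatrix(values=values, ids=row_ids, kind=kind)


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Record config, seed and version so a run can be reproduced exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
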