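"""Self-contained synthetic fixtures: ontology DAGs and planted associations.

The association generator plants a stochastic block structure: lncRNAs and
diseases are split into matching groups and pairs inside a matched group
associate with probability ``density_in``, all other pairs with
``density_out``.  Defaults emulate the scale of the curated human
lncRNA-disease dataset the method targets (156 lncRNAs x 190 diseases,
~350 known associations), i.e. a very sparse binary bipartite matrix.
All generators are deterministic given spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .similarity import AssociationMatrix

__all__ = [
    "SyntheticSpec",
    "generate_dag_forest",
    "generate_full_tree",
    "generate_association_matrix",
    "mask_entries",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    nl: int = 156
    nd: int = 190
    n_blocks: int = 4
    density_in: float = 0.04
    density_out: float = 0.003
    dag_depth: int = 4
    branching: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.density_out < self.density_in <= 1.0):
            raise ValueError("need 0 <= density_out < density_in <= 1")
        if self.nl < self.n_blocks or self.nd < self.n_blocks:
            raise ValueError("each side needs at least one node per block")
        if self.dag_depth < 1 or self.branching < 1:
            raise ValueError("dag_depth and branching must be >= 1")

    @property
    def disease_ids(self) -> tuple:
        return tuple(f"D{i:04d}" for i in range(self.nd))

    @property
    def lncrna_ids(self) -> tuple:
        return tuple(f"L{i:04d}" for i in range(self.nl))


def generate_dag_forest(spec: SyntheticSpec) -> list:
    """Random rooted ontology covering every disease id, as (child, parent).

    Node 0 is the root; every later node attaches to an earlier node of
    depth < dag_depth (preferring parents with fewer than ``branching``
    children) and occasionally gains a second parent, so the result is a
    DAG by construction.  ``dag_depth=1`` yields a star under the root.
    """
    rng = np.random.default_rng([spec.seed, 101])
    ids = spec.disease_ids
    depth = {0: 0}
    child_count = {0: 0}
    edges = []
    for i in range(1, spec.nd):
        eligible = [j for j in range(i) if depth[j] < spec.dag_depth]
        preferred = [j for j in eligible if child_count[j] < spec.branching]
        pool = preferred if preferred else eligible
        parent = int(rng.choice(pool))
        edges.append((ids[i], ids[parent]))
        child_count[parent] += 1
        depth[i] = depth[parent] + 1
        child_count[i] = 0
        # occasional second parent keeps genuine DAG (not just tree) shapes
        others = [j for j in eligible if j != parent]
        if others and rng.random() < 0.15:
            second = int(rng.choice(others))
            edges.append((ids[i], ids[second]))
            child_count[second] += 1
    return edges


def generate_full_tree(depth: int, branching: int, prefix: str = "N") -> list:
    """Complete ``branching``-ary tree edge list; handy for exact counting."""
    edges = []
    nodes = [f"{prefix}0"]
    counter = 1
    frontier = [nodes[0]]
    for _ in range(depth):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                child = f"{prefix}{counter}"
                counter += 1
                edges.append((child, parent))
                nxt.append(child)
        frontier = nxt
    return edges


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    sizes = [len(part) for part in np.array_split(np.arange(n), n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


def generate_association_matrix(spec: SyntheticSpec):
    """Planted block-structured binary matrix plus ground-truth labels.

    Returns ``(assoc, labels)`` where ``labels`` maps 'lncrna' and
    'disease' to block-index arrays for recovery scoring.
    """
    rng = np.random.default_rng([spec.seed, 202])
    l_labels = _block_labels(spec.nl, spec.n_blocks)
    d_labels = _block_labels(spec.nd, spec.n_blocks)
    same_block = l_labels[:, None] == d_labels[None, :]
    prob = np.where(same_block, spec.density_in, spec.density_out)
    if prob.max() == 0.0:
        raise ValueError("degenerate spec: the expected matrix is all-zero")
    values = (rng.random((spec.nl, spec.nd)) < prob).astype(float)
    if values.sum() == 0:
        raise ValueError("no associations drawn; increase densities or size")
    assoc = AssociationMatrix(values=values, lncrna_ids=spec.lncrna_ids,
                              disease_ids=spec.disease_ids)
    return assoc, {"lncrna": l_labels, "disease": d_labels}


def mask_entries(assoc: AssociationMatrix, fraction: float = 0.2,
                 seed: int = 0, column: Optional[str] = None):
    """Hold out positives for testing; returns (train assoc, held-out pairs).

    Uniform mode removes ``round(fraction * n_positives)`` positives.
    Column mode instead zeroes the whole column of one disease, the
    cold-start condition (an entirely missing column).
    """
    values = assoc.values.copy()
    if column is not None:
        j = assoc.disease_ids.index(column)
        held = [(int(i), j) for i in np.nonzero(values[:, j])[0]]
        if len(held) == values.sum():
            raise ValueError("masking this column would remove every positive")
        values[:, j] = 0.0
    else:
        if not (0.0 < fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")
        pos = assoc.positives()
        n_remove = round(fraction * len(pos))
        if n_remove >= len(pos):
            raise ValueError("masking would remove every positive")
        rng = np.random.default_rng([seed, 303])
        idx = rng.choice(len(pos), size=n_remove, replace=False)
        held = [pos[i] for i in sorted(idx.tolist())]
        for i, j in held:
            values[i, j] = 0.0
    train = AssociationMatrix(values=values, lncrna_ids=assoc.lncrna_ids,
                              disease_ids=assoc.disease_ids)
    return train, held
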