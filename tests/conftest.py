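"""Shared fixtures: small planted datasets and scaled-down run configs."""

from __future__ import annotations

import numpy as np
import pytest

from gatimc import (
    RunConfig,
    SyntheticSpec,
    generate_association_matrix,
    generate_dag_forest,
    semantic_similarity_from_edges,
)


def small_config(**overrides) -> RunConfig:
    """Desk-scale training config used throughout the test suite."""
    base = dict(n_heads=2, neurons=8, rank=16, epochs=150, lr=0.02)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def planted_small():
    """20x30 rank-2 planted matrix with strong signal (recovery tests)."""
    spec = SyntheticSpec(nl=20, nd=30, n_blocks=2, density_in=0.9,
                         density_out=0.05, seed=0)
    assoc, labels = generate_association_matrix(spec)
    ds = semantic_similarity_from_edges(assoc.disease_ids,
                                        generate_dag_forest(spec))
    return assoc, ds, spec, labels


@pytest.fixture(scope="session")
def planted_main():
    """The 60x80 2-block synthetic study fixture (density 0.3 / 0.01)."""
    spec = SyntheticSpec(nl=60, nd=80, n_blocks=2, density_in=0.3,
                         density_out=0.01, seed=0)
    assoc, labels = generate_association_matrix(spec)
    ds = semantic_similarity_from_edges(assoc.disease_ids,
                                        generate_dag_forest(spec))
    # true planted Bernoulli probabilities, lncRNA x disease
    same = labels["lncrna"][:, None] == labels["disease"][None, :]
    prob = np.where(same, spec.density_in, spec.density_out)
    return assoc, ds, spec, prob


# ---------------------------------------------------------------------------
# Independent oracles (used by unit and acceptance tests)
# ---------------------------------------------------------------------------

def random_dag(rng: np.random.Generator, max_nodes: int = 10):
    """Random DAG edge list over string ids; parents always earlier nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        edges.extend((ids[i], ids[int(p)]) for p in parents)
    return ids, edges


def oracle_contributions(disease: str, edges, gamma: float) -> dict:
    """Brute-force contribution oracle: max over upward paths of gamma**len."""
    parents: dict = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
        parents.setdefault(p, set())
    best = {disease: 1.0}
    stack = [(disease, 1.0)]
    while stack:
        node, val = stack.pop()
        for par in parents.get(node, ()):  # enumerate every upward path
            cand = val * gamma
            if cand > best.get(par, 0.0):
                best[par] = cand
            stack.append((par, cand))
    return best


def oracle_semantic_matrix(disease_ids, edges, gamma: float) -> np.ndarray:
    """Pairwise semantic similarity from the brute-force contributions."""
    contribs = [oracle_contributions(d, edges, gamma) for d in disease_ids]
    sem = [sum(c.values()) for c in contribs]
    n = len(disease_ids)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][m] + contribs[j][m] for m in shared)
                out[i, j] = out[j, i] = num / (sem[i] + sem[j])
    return out


def oracle_roc_auc(scores, labels) -> float:
    """Pairwise Mann-Whitney counting with the ties-as-half convention."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_pr_auc(scores, labels) -> float:
    """Exhaustive threshold enumeration, step-wise area (no interpolation)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(s.tolist()), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def oracle_multi_operator(h_i, h_Ni, W1_sum, W1_cat, slope):
    """Scalar-loop reference for the three-operator head combiner."""
    d = len(h_i)
    k = W1_sum.shape[1]
    cat = list(h_i) + list(h_Ni)
    out = []
    for c in range(k):
        s = 0.0
        for a in range(d):
            s += (h_i[a] + h_Ni[a]) * W1_sum[a, c]
        s = s if s > 0 else slope * s
        cc = 0.0
        for a in range(2 * d):
            cc += cat[a] * W1_cat[a, c]
        cc = cc if cc > 0 else slope * cc
        out.append(s + cc + s * cc)
    return np.array(out)
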