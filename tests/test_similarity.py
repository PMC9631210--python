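"""Unit tests for the similarity networks (semantic, functional, GIP, integration)."""

import numpy as np
import pytest

from gatimc.similarity import (
    AssociationMatrix,
    OntologyError,
    SimilarityMatrix,
    assemble_feature_matrix,
    build_disease_dag,
    disease_semantic_similarity,
    gaussian_kernel,
    gaussian_similarity,
    integrate_disease_similarity,
    integrate_lncrna_similarity,
    lncrna_functional_similarity,
    semantic_similarity_from_edges,
    semantic_value,
)

from conftest import oracle_semantic_matrix, random_dag


# ---------------------------------------------------------------------------
# build_disease_dag / semantic_value
# ---------------------------------------------------------------------------

def test_dag_chain_contributions():
    edges = [("d", "p"), ("p", "g")]
    dag = build_disease_dag("d", edges, gamma=0.5)
    assert dag.contributions == {"d": 1.0, "p": 0.5, "g": 0.25}
    assert semantic_value(dag) == pytest.approx(1.75, abs=1e-15)


def test_dag_isolated_disease():
    dag = build_disease_dag("d", [("x", "d")])  # d has no parents
    assert dag.contributions == {"d": 1.0}
    assert semantic_value(dag) == 1.0


def test_dag_diamond():
    # d -> p1, d -> p2, p1 -> g, p2 -> g: g reached via two 2-edge paths
    edges = [("d", "p1"), ("d", "p2"), ("p1", "g"), ("p2", "g")]
    dag = build_disease_dag("d", edges, gamma=0.5)
    assert dag.contributions == {"d": 1.0, "p1": 0.5, "p2": 0.5, "g": 0.25}
    assert semantic_value(dag) == pytest.approx(2.25, abs=1e-15)


def test_dag_unknown_disease():
    with pytest.raises(KeyError):
        build_disease_dag("missing", [("a", "b")])


def test_dag_cycle_detected():
    with pytest.raises(OntologyError):
        build_disease_dag("d", [("d", "a"), ("a", "b"), ("b", "a")])


def test_dag_gamma_validation():
    for bad in (0.0, 1.0, -0.5, 2.0):
        with pytest.raises(ValueError):
            build_disease_dag("d", [("d", "p")], gamma=bad)


def test_dag_contributions_in_unit_interval():
    rng = np.random.default_rng(5)
    for _ in range(20):
        ids, edges = random_dag(rng)
        dag = build_disease_dag(ids[-1], edges if edges else [(ids[-1], ids[0])])
        assert dag.contributions[dag.disease_id] == 1.0
        assert all(0.0 < c <= 1.0 for c in dag.contributions.values())


# ---------------------------------------------------------------------------
# disease_semantic_similarity
# ---------------------------------------------------------------------------

def test_semantic_self_similarity_is_one():
    edges = [("a", "r"), ("b", "r"), ("c", "b")]
    ds = semantic_similarity_from_edges(("a", "b", "c", "r"), edges)
    assert np.allclose(np.diag(ds.values), 1.0)


def test_semantic_disjoint_dags_zero():
    edges = [("a", "pa"), ("b", "pb")]
    ds = semantic_similarity_from_edges(("a", "b"), edges)
    assert ds.values[0, 1] == 0.0


def test_semantic_siblings_third():
    # a and b are siblings under p: shared={p}, (0.5+0.5)/(1.5+1.5) = 1/3
    edges = [("a", "p"), ("b", "p")]
    ds = semantic_similarity_from_edges(("a", "b"), edges)
    assert ds.values[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-15)


def test_semantic_requires_shared_gamma():
    d1 = build_disease_dag("a", [("a", "p")], gamma=0.5)
    d2 = build_disease_dag("b", [("b", "p")], gamma=0.4)
    with pytest.raises(ValueError):
        disease_semantic_similarity([d1, d2])


def test_semantic_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        ids, edges = random_dag(rng)
        if not edges:
            continue
        ds = semantic_similarity_from_edges(ids, edges, gamma=0.5)
        oracle = oracle_semantic_matrix(ids, edges, gamma=0.5)
        assert np.abs(ds.values - oracle).max() <= 1e-12


# ---------------------------------------------------------------------------
# lncrna_functional_similarity
# ---------------------------------------------------------------------------

def _ds_matrix(vals, ids):
    return SimilarityMatrix(values=np.asarray(vals, float), ids=ids,
                            kind="semantic")


def test_functional_shared_single_disease():
    assoc = AssociationMatrix(values=np.array([[1.0, 0.0], [1.0, 0.0]]),
                              lncrna_ids=("l1", "l2"), disease_ids=("d1", "d2"))
    ds = _ds_matrix([[1.0, 0.2], [0.2, 1.0]], ("d1", "d2"))
    fs = lncrna_functional_similarity(assoc, ds)
    assert fs.values[0, 1] == 1.0
    assert fs.values[0, 0] == 1.0  # self-similarity with >=1 association


def test_functional_single_distinct_diseases():
    s = 0.37
    assoc = AssociationMatrix(values=np.array([[1.0, 0.0], [0.0, 1.0]]),
                              lncrna_ids=("l1", "l2"), disease_ids=("d1", "d2"))
    ds = _ds_matrix([[1.0, s], [s, 1.0]], ("d1", "d2"))
    fs = lncrna_functional_similarity(assoc, ds)
    assert fs.values[0, 1] == pytest.approx(s, abs=1e-15)  # (s+s)/2


def test_functional_empty_association_row():
    assoc = AssociationMatrix(values=np.array([[1.0, 1.0], [0.0, 0.0]]),
                              lncrna_ids=("l1", "l2"), disease_ids=("d1", "d2"))
    ds = _ds_matrix(np.eye(2), ("d1", "d2"))
    with pytest.warns(UserWarning, match="no known associations"):
        fs = lncrna_functional_similarity(assoc, ds)
    assert (fs.values[1] == 0.0).all()
    assert (fs.values[:, 1] == 0.0).all()


def test_functional_best_match_average_oracle():
    # l1 -> {d1, d2}, l2 -> {d2, d3}; hand best-match-average
    assoc = AssociationMatrix(
        values=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]),
        lncrna_ids=("l1", "l2"), disease_ids=("d1", "d2", "d3"))
    D = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.6], [0.1, 0.6, 1.0]])
    ds = _ds_matrix(D, ("d1", "d2", "d3"))
    fs = lncrna_functional_similarity(assoc, ds)
    # best matches of {d1,d2} in {d2,d3}: max(0.4,0.1)=0.4, max(1,.6)=1
    # best matches of {d2,d3} in {d1,d2}: max(.4,1)=1, max(.1,.6)=0.6
    expected = (0.4 + 1.0 + 1.0 + 0.6) / 4.0
    assert fs.values[0, 1] == pytest.approx(expected, abs=1e-15)


def test_functional_requires_covering_semantic_matrix():
    assoc = AssociationMatrix(values=np.array([[1.0]]),
                              lncrna_ids=("l1",), disease_ids=("d1",))
    ds = _ds_matrix(np.eye(1), ("other",))
    with pytest.raises(ValueError):
        lncrna_functional_similarity(assoc, ds)


# ---------------------------------------------------------------------------
# gaussian_kernel / gaussian_similarity
# ---------------------------------------------------------------------------

def test_gip_identical_profiles():
    gk = gaussian_kernel(np.array([[1.0, 0.0], [1.0, 0.0]]), ("a", "b"))
    assert gk.values[0, 1] == 1.0


def test_gip_two_profile_closed_form():
    gk = gaussian_kernel(np.array([[1.0, 0.0], [0.0, 1.0]]), ("a", "b"))
    assert abs(gk.values[0, 1] - np.exp(-2.0)) <= 1e-12


def test_gip_symmetric_unit_diagonal_and_bounds():
    rng = np.random.default_rng(3)
    P = (rng.random((8, 5)) < 0.4).astype(float)
    P[0] = 1.0  # guarantee a nonzero profile
    gk = gaussian_kernel(P, tuple(f"n{i}" for i in range(8)))
    assert np.allclose(gk.values, gk.values.T)
    assert np.allclose(np.diag(gk.values), 1.0)
    assert ((gk.values > 0.0) & (gk.values <= 1.0)).all()


def test_gip_permutation_invariance():
    rng = np.random.default_rng(4)
    P = (rng.random((7, 6)) < 0.5).astype(float)
    P[0] = 1.0
    ids = tuple(f"n{i}" for i in range(7))
    perm = rng.permutation(7)
    gk = gaussian_kernel(P, ids)
    gk_p = gaussian_kernel(P[perm], tuple(ids[i] for i in perm))
    assert np.allclose(gk_p.values, gk.values[np.ix_(perm, perm)], atol=1e-15)


def test_gip_all_zero_profiles_rejected():
    with pytest.raises(ValueError, match="bandwidth"):
        gaussian_kernel(np.zeros((3, 4)), ("a", "b", "c"))


def test_gaussian_similarity_axes():
    assoc = AssociationMatrix(values=np.array([[1.0, 0.0], [0.0, 1.0]]),
                              lncrna_ids=("l1", "l2"), disease_ids=("d1", "d2"))
    gd = gaussian_similarity(assoc, "disease")
    gl = gaussian_similarity(assoc, "lncrna")
    assert gd.ids == ("d1", "d2") and gl.ids == ("l1", "l2")
    with pytest.raises(ValueError):
        gaussian_similarity(assoc, "bogus")


# ---------------------------------------------------------------------------
# integration and assembly
# ---------------------------------------------------------------------------

def test_integrate_disease_branches():
    ids = ("a", "b")
    ds = _ds_matrix([[1.0, 0.0], [0.0, 1.0]], ids)
    gd = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ids, "gaussian")
    out = integrate_disease_similarity(ds, gd)
    assert out.values[0, 1] == 0.4  # DS=0 branch: GD alone
    assert out.values[0, 0] == 2.0  # DS=1 branch: literal sum, may exceed 1

    ds2 = _ds_matrix([[1.0, 0.3], [0.3, 1.0]], ids)
    out2 = integrate_disease_similarity(ds2, gd)
    assert out2.values[0, 1] == pytest.approx(0.7, abs=1e-15)


def test_integrate_disease_all_zero_semantic_collapses_to_gip():
    ids = ("a", "b")
    ds = SimilarityMatrix(np.zeros((2, 2)), ids, "semantic")
    gd = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ids, "gaussian")
    out = integrate_disease_similarity(ds, gd)
    assert np.array_equal(out.values, gd.values)


def test_integrate_disease_average_flag():
    ids = ("a", "b")
    ds = _ds_matrix([[1.0, 0.3], [0.3, 1.0]], ids)
    gd = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ids, "gaussian")
    out = integrate_disease_similarity(ds, gd, average=True)
    assert out.values[0, 1] == pytest.approx(0.35, abs=1e-15)


def test_integrate_lncrna_branches_no_sum():
    ids = ("a", "b")
    fs = SimilarityMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]), ids, "functional")
    gl = SimilarityMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]), ids, "gaussian")
    out = integrate_lncrna_similarity(fs, gl)
    assert out.values[0, 1] == 0.6  # FS nonzero wins, no addition

    fs0 = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ids, "functional")
    out0 = integrate_lncrna_similarity(fs0, gl)
    assert out0.values[0, 1] == 0.2  # FS=0 branch: GL


def test_integration_alignment_error():
    fs = SimilarityMatrix(np.eye(2), ("a", "b"), "functional")
    gl = SimilarityMatrix(np.eye(2), ("a", "c"), "gaussian")
    with pytest.raises(ValueError):
        integrate_lncrna_similarity(fs, gl)


def test_integrate_lncrna_pass_through_idempotent():
    ids = ("a", "b", "c")
    rng = np.random.default_rng(9)
    v = rng.random((3, 3))
    v = (v + v.T) / 2
    fs = SimilarityMatrix(v * (v > 0.3), ids, "functional")
    gl = SimilarityMatrix((v + v.T) / 2 + np.eye(3) * 0.01, ids, "gaussian")
    once = integrate_lncrna_similarity(fs, gl)
    fs_once = SimilarityMatrix(once.values, ids, "functional")
    twice = integrate_lncrna_similarity(fs_once, SimilarityMatrix(
        once.values, ids, "gaussian"))
    assert np.array_equal(once.values, twice.values)


def test_assemble_feature_matrix_layout():
    ids_d = ("d1", "d2")
    ids_l = ("l1", "l2", "l3")
    ds_i = SimilarityMatrix(np.full((2, 2), 0.5) + 0.5 * np.eye(2), ids_d,
                            "integrated")
    fs_i = SimilarityMatrix(np.full((3, 3), 0.25) + 0.75 * np.eye(3), ids_l,
                            "integrated")
    X = assemble_feature_matrix(ds_i, fs_i)
    assert X.values.shape == (5, 5)
    assert np.array_equal(X.values[:2, 3:], ds_i.values)   # DS(I) block
    assert np.array_equal(X.values[2:, :3], fs_i.values)   # FS(I) block
    assert (X.values[:2, :3] == 0.0).all()                 # zero blocks
    assert (X.values[2:, 3:] == 0.0).all()


def test_assemble_zero_inputs_all_zero():
    ds_i = SimilarityMatrix(np.zeros((2, 2)), ("d1", "d2"), "integrated")
    fs_i = SimilarityMatrix(np.zeros((2, 2)), ("l1", "l2"), "integrated")
    X = assemble_feature_matrix(ds_i, fs_i)
    assert (X.values == 0.0).all()


# ---------------------------------------------------------------------------
# type invariants
# ---------------------------------------------------------------------------

def test_association_matrix_validation():
    with pytest.raises(ValueError):
        AssociationMatrix(values=np.array([[0.5]]), lncrna_ids=("l",),
                          disease_ids=("d",))
    with pytest.raises(ValueError):
        AssociationMatrix(values=np.zeros((2, 1)), lncrna_ids=("l", "l"),
                          disease_ids=("d",))


def test_similarity_matrix_symmetry_enforced():
    with pytest.raises(ValueError):
        SimilarityMatrix(np.array([[1.0, 0.2], [0.4, 1.0]]), ("a", "b"),
                         "semantic")
    with pytest.raises(ValueError):
        SimilarityMatrix(np.eye(2), ("a", "b"), "bogus-kind")
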