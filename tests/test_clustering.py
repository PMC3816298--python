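"""Dendrograms, cuts, newick export, tree comparison, heatmap ordering."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist

from spectrabin import (
    ProfileMatrix,
    cluster,
    compare_trees,
    cut,
    distance_matrix,
    heatmap_export,
    monophyly_check,
    to_newick,
)


def pm_from(values, ids=None, motifs=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    motifs = motifs or tuple(f"m{j}" for j in range(values.shape[1]))
    return ProfileMatrix("TEST", list(ids), tuple(motifs), values)


THREE_POINTS = pm_from([[0.9, 0.1], [0.88, 0.12], [0.1, 0.9]], ids=["P1", "P2", "P3"])


# ------------------------------------------------------------- distances


@pytest.mark.parametrize(
    "metric,expected", [("euclidean", 5.0), ("manhattan", 7.0)]
)
def test_distance_matrix_values(metric, expected):
    D = distance_matrix(pm_from([[0.0, 0.0], [3.0, 4.0]]), metric)
    assert D.shape == (2, 2)
    assert D[0, 0] == D[1, 1] == 0.0
    assert D[0, 1] == D[1, 0] == pytest.approx(expected)


def test_distance_matrix_identical_rows_and_errors():
    assert distance_matrix(pm_from([[1, 2], [1, 2]]))[0, 1] == 0.0
    with pytest.raises(ValueError):
        distance_matrix(pm_from([[1.0, 2.0]]))  # single row
    with pytest.raises(ValueError):
        distance_matrix(np.array([[1.0, np.nan], [0.0, 1.0]]))
    with pytest.raises(ValueError):
        distance_matrix(pm_from([[1, 1], [0, 1]]), "correlation")  # constant row


# ------------------------------------------------------------- clustering


def test_three_point_merge_order_and_heights():
    dend = cluster(THREE_POINTS)
    # nearest pair (P1, P2) merges first, at their Euclidean distance
    assert set(dend.linkage[0, :2]) == {0.0, 1.0}
    assert dend.linkage[0, 2] == pytest.approx(math.hypot(0.02, 0.02))
    # complete linkage: P3 joins at max(d(P3,P1), d(P3,P2))
    assert dend.linkage[1, 2] == pytest.approx(math.hypot(0.8, 0.8))


def test_identical_rows_merge_at_height_zero_with_deterministic_ties():
    dend = cluster(pm_from(np.ones((4, 3))))
    assert np.all(dend.heights == 0.0)
    # ties resolved toward the smallest cluster-id pair: (0,1) then (2,3)
    assert list(dend.linkage[0, :2]) == [0.0, 1.0]
    assert list(dend.linkage[1, :2]) == [2.0, 3.0]


@pytest.mark.parametrize("method", ["complete", "average", "single"])
def test_merge_heights_are_monotone(method):
    rng = np.random.default_rng(7)
    dend = cluster(pm_from(rng.random((12, 5))), linkage=method)
    assert np.all(np.diff(dend.heights) >= -1e-12)


@pytest.mark.parametrize("method", ["complete", "average", "single"])
def test_agglomeration_agrees_with_scipy_on_tie_free_data(method):
    """Independent route: scipy's linkage gives the same hierarchy (checked
    via cophenetic distances) when all dissimilarities are distinct."""
    rng = np.random.default_rng(11)
    X = rng.random((15, 4))
    dend = cluster(pm_from(X), linkage=method)
    Z_ref = scipy_linkage(pdist(X), method=method)
    np.testing.assert_allclose(cophenet(dend.linkage), cophenet(Z_ref), rtol=1e-12)


def test_clustering_invariant_under_row_permutation():
    rng = np.random.default_rng(3)
    X = rng.random((10, 4))
    ids = [f"s{i}" for i in range(10)]
    nwk1 = to_newick(cluster(pm_from(X, ids=ids)))
    perm = rng.permutation(10)
    nwk2 = to_newick(cluster(pm_from(X[perm], ids=[ids[i] for i in perm])))
    assert compare_trees(nwk1, nwk2) == 0


# ------------------------------------------------------------- cutting


def test_cut_three_points():
    dend = cluster(THREE_POINTS)
    two = cut(dend, 2)
    assert two.labels == {"P1": 1, "P2": 1, "P3": 2}
    assert cut(dend, 1).labels == {"P1": 1, "P2": 1, "P3": 1}
    assert sorted(cut(dend, 3).labels.values()) == [1, 2, 3]
    for bad_k in (0, 4):
        with pytest.raises(ValueError):
            cut(dend, bad_k)


def test_cut_recovers_planted_partition():
    """Two groups with >= 10x between/within separation are recovered exactly."""
    rng = np.random.default_rng(5)
    a = 0.01 * rng.random((6, 4))
    b = 0.01 * rng.random((5, 4)) + 1.0
    X = np.vstack([a, b])
    perm = rng.permutation(11)
    ids = [f"g{'A' if i < 6 else 'B'}{i}" for i in range(11)]
    assignment = cut(cluster(pm_from(X[perm], ids=[ids[i] for i in perm])), 2)
    groups = {}
    for seq_id, label in assignment.labels.items():
        groups.setdefault(label, set()).add(seq_id[1])
    assert sorted(groups.values(), key=len) == [{"B"}, {"A"}]


# ------------------------------------------------------------- newick / RF


def test_two_leaf_newick_uses_midpoint_branches():
    dend = cluster(pm_from([[0.0, 0.0], [3.0, 4.0]], ids=["A", "B"]))
    assert to_newick(dend) == "(A:2.5,B:2.5);"


def test_newick_round_trip_preserves_topology_and_labels():
    import dendropy

    rng = np.random.default_rng(13)
    ids = [f"leaf {i}" for i in range(8)]  # spaces force quoting
    dend = cluster(pm_from(rng.random((8, 3)), ids=ids))
    nwk = to_newick(dend)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(ids)
    rewritten = tree.as_string(schema="newick")
    assert compare_trees(nwk, rewritten) == 0


def test_newick_branch_lengths_embed_merge_heights():
    dend = cluster(THREE_POINTS)
    import dendropy

    tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    # cophenetic distance between leaves equals their merge height
    assert pdm.distance(taxa["P1"], taxa["P2"]) == pytest.approx(dend.heights[0])
    assert pdm.distance(taxa["P1"], taxa["P3"]) == pytest.approx(dend.heights[1])


def test_robinson_foulds_cases():
    same = "((A:1,B:1):1,(C:1,D:1):1);"
    assert compare_trees(same, same) == 0
    swapped = "((A:1,C:1):1,(B:1,D:1):1);"
    # hand enumeration: each 4-leaf tree has one non-trivial bipartition
    # (AB|CD vs AC|BD); the symmetric difference holds both, so RF = 2
    assert compare_trees(same, swapped) == 2
    with pytest.raises(ValueError, match="E"):
        compare_trees(same, "((A:1,B:1):1,(C:1,E:1):1);")


def test_monophyly_check_reports_clades():
    rng = np.random.default_rng(23)
    X = np.vstack([
        0.01 * rng.random((3, 4)),
        0.01 * rng.random((3, 4)) + 1.0,
        0.01 * rng.random((3, 4)) + 5.0,
    ])
    ids = [f"{g}{i}" for g in "abc" for i in range(3)]
    dend = cluster(pm_from(X, ids=ids))
    groups = {g: [f"{g}{i}" for i in range(3)] for g in "abc"}
    assert monophyly_check(dend, groups) == {"a": True, "b": True, "c": True}
    mixed = {"a": ["a0", "a1", "b0"], "b": ["a2", "b1", "b2"],
             "c": ["c0", "c1", "c2"]}
    result = monophyly_check(dend, mixed)
    assert result == {"a": False, "b": False, "c": True}
    with pytest.raises(ValueError):
        monophyly_check(dend, {"a": ["a0"]})  # not a partition of the leaves


# ------------------------------------------------------------- heatmap


def test_heatmap_export_reorders_without_changing_values():
    dend = cluster(THREE_POINTS)
    export = heatmap_export(THREE_POINTS, dend, scale="none")
    assert set(export.row_order) == {"P1", "P2", "P3"}
    df = THREE_POINTS.to_dataframe()
    assert export.frame.equals(df.loc[export.row_order])


def test_heatmap_column_z_scaling_is_display_only():
    rng = np.random.default_rng(2)
    X = rng.random((6, 4))
    X[:, 3] = 0.25  # zero-variance column
    pm = pm_from(X)
    export = heatmap_export(pm, cluster(pm), scale="column_z")
    np.testing.assert_allclose(export.frame.values[:, :3].mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(export.frame.values[:, :3].std(axis=0), 1.0, atol=1e-12)
    assert np.all(export.frame.values[:, 3] == 0.0)


def test_heatmap_export_rejects_leaf_mismatch():
    dend = cluster(THREE_POINTS)
    other = pm_from(np.random.default_rng(0).random((3, 2)), ids=["X", "Y", "Z"])
    with pytest.raises(ValueError):
        heatmap_export(other, dend)
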