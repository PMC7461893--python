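import json

import numpy as np
import pytest

from semkos.embedding import VectorTable
from semkos.tree_kos import (
    KOS,
    MergeTree,
    agglomerate_average_linkage,
    annotate_cluster,
    annotate_from_cut,
    branch_terms,
    cluster_representation,
    cut_tree,
    export_tree,
    layout_landscape,
    pairwise_distances,
    read_kos_tsv,
    regroup_level3,
    sample_branch_for_review,
    tree_from_json,
    write_kos_tsv,
)
from _oracles import naive_upgma


def random_distance_matrix(n, rng, integer=False):
    a = rng.integers(1, 10, size=(n, n)).astype(float) if integer else rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture
def spec_tree():
    # d(1,2)=1, d(3,4)=2, all cross distances 10
    d = np.full((4, 4), 10.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 2.0
    return agglomerate_average_linkage(d, ["t1", "t2", "t3", "t4"])


def test_two_leaves_single_merge():
    d = np.array([[0.0, 3.5], [3.5, 0.0]])
    tree = agglomerate_average_linkage(d, ["a", "b"])
    assert tree.merges == [(1, 2, 3.5)]
    assert tree.root == 3


def test_hand_worked_four_leaf_case(spec_tree):
    assert spec_tree.merges[0] == (1, 2, 1.0)  # creates node 5
    assert spec_tree.merges[1] == (3, 4, 2.0)  # creates node 6
    assert spec_tree.merges[2] == (5, 6, 10.0)  # root 7; cross average stays 10


def test_merge_sequence_matches_naive_oracle():
    rng = np.random.default_rng(11)
    for trial in range(40):
        n = int(rng.integers(2, 31))
        d = random_distance_matrix(n, rng, integer=bool(trial % 2))
        tree = agglomerate_average_linkage(d)
        assert tree.merges == naive_upgma(d)


def test_agreement_with_scipy_average_linkage():
    # independent library cross-check on a tie-free matrix: the multiset of
    # merge heights must coincide with scipy's average-linkage heights
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    d = random_distance_matrix(25, rng)
    tree = agglomerate_average_linkage(d)
    Z = linkage(squareform(d, checks=False), method="average")
    np.testing.assert_allclose(
        sorted(h for _, _, h in tree.merges), np.sort(Z[:, 2]), rtol=1e-10
    )


def test_tree_conventions_hold_on_random_trees():
    rng = np.random.default_rng(5)
    for _ in range(15):
        n = int(rng.integers(2, 40))
        tree = agglomerate_average_linkage(random_distance_matrix(n, rng))
        labels = set(range(1, 2 * n))
        seen = set(range(1, n + 1))
        heights = [h for _, _, h in tree.merges]
        assert heights == sorted(heights)
        for k, (a, b, _) in enumerate(tree.merges, start=1):
            created = n + k
            assert a < created and b < created
            assert a in seen and b in seen
            seen.add(created)
        assert seen == labels
        assert len(branch_terms(tree, tree.root)) == n
        for node in range(n + 1, 2 * n):
            a, b = tree.children(node)
            assert len(tree.leaves_under(node)) == len(tree.leaves_under(a)) + len(
                tree.leaves_under(b)
            )


def test_degenerate_matrices_rejected():
    with pytest.raises(ValueError):
        agglomerate_average_linkage(np.zeros((1, 1)))
    with pytest.raises(ValueError):
        agglomerate_average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


def test_pairwise_distances_closed_forms():
    table = VectorTable(
        {
            "a": np.array([1.0, 0.0]),
            "b": np.array([1.0, 0.0]),
            "c": np.array([0.0, 1.0]),
        },
        {},
    )
    d = pairwise_distances(table, ["a", "b", "c"])
    assert d[0, 1] == pytest.approx(0.0)
    assert d[0, 2] == pytest.approx(np.sqrt(2.0))
    np.testing.assert_allclose(d, d.T)
    assert np.all(np.diag(d) == 0)
    with pytest.raises(KeyError):
        pairwise_distances(table, ["a", "missing"])


def test_branch_terms_leaf_root_and_union(spec_tree):
    assert branch_terms(spec_tree, 1) == ["t1"]
    assert branch_terms(spec_tree, 7) == ["t1", "t2", "t3", "t4"]
    assert branch_terms(spec_tree, 5) == ["t1", "t2"]
    assert set(branch_terms(spec_tree, 7)) == set(branch_terms(spec_tree, 5)) | set(
        branch_terms(spec_tree, 6)
    )
    with pytest.raises(ValueError):
        branch_terms(spec_tree, 99)


def test_cut_tree_extremes(spec_tree):
    assert cut_tree(spec_tree, 1) == [{"t1", "t2", "t3", "t4"}]
    assert sorted(cut_tree(spec_tree, 2), key=min) == [{"t1", "t2"}, {"t3", "t4"}]
    assert sorted(map(sorted, cut_tree(spec_tree, 4))) == [["t1"], ["t2"], ["t3"], ["t4"]]


def test_branch_sampling_budget_and_determinism(spec_tree):
    assert sorted(sample_branch_for_review(spec_tree, 7, budget=10, seed=0)) == [
        "t1",
        "t2",
        "t3",
        "t4",
    ]
    two = sample_branch_for_review(spec_tree, 7, budget=2, seed=1)
    assert len(two) == 2
    assert len({t for t in two} & {"t1", "t2"}) == 1  # one from each child subtree
    assert len({t for t in two} & {"t3", "t4"}) == 1
    assert sample_branch_for_review(spec_tree, 7, budget=2, seed=1) == two
    with pytest.raises(ValueError):
        sample_branch_for_review(spec_tree, 99, budget=2)


def test_annotation_and_paraphyletic_union(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "first pair")
    # two sibling branches under one shared name (paraphyletic union)
    annotate_cluster(kos, {3, 4}, "second pair")
    assert kos.members(kos.annotation_by_name("second pair")) == ["t3", "t4"]
    assert kos.term_cluster("t1") == "first pair"
    assert kos.term_cluster("t3") == "second pair"


def test_annotation_overlap_error_lists_conflicts(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "first pair")
    with pytest.raises(ValueError, match="t1"):
        annotate_cluster(kos, {7}, "everything")
    with pytest.raises(ValueError):
        annotate_cluster(kos, {42}, "bad node")


def test_annotation_log_is_append_only(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "a")
    annotate_cluster(kos, {6}, "b")
    assert [e["name"] for e in kos.log] == ["a", "b"]


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def test_cluster_representation_mean_not_renormalized(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "pair")
    table = VectorTable(
        {"t1": _unit([1, 0]), "t2": _unit([0, 1]), "t3": _unit([1, 0]), "t4": _unit([-1, 0])},
        {},
    )
    rep = cluster_representation(kos, kos.annotation_by_name("pair"), table)
    np.testing.assert_allclose(rep, [0.5, 0.5])
    # two opposite unit vectors average to zero
    annotate_cluster(kos, {3, 4}, "opposed")
    rep2 = cluster_representation(kos, kos.annotation_by_name("opposed"), table)
    np.testing.assert_allclose(rep2, [0.0, 0.0], atol=1e-15)


def test_regroup_level3_recovers_planted_supergroups():
    # 6 level-2 clusters in two well-separated super-groups
    rng = np.random.default_rng(0)
    centers = {0: np.array([10.0, 0.0]), 1: np.array([-10.0, 0.0])}
    terms, vectors = [], {}
    for c in range(6):
        for t in range(3):
            name = f"c{c}t{t}"
            terms.append(name)
            vectors[name] = _unit(centers[c % 2] + rng.normal(0, 0.05, 2))
    table = VectorTable(vectors, {})
    tree = agglomerate_average_linkage(pairwise_distances(table, terms), terms)
    kos = annotate_from_cut(KOS(tree), 6)
    regroup_level3(kos, table, n_groups=2)
    assert len(kos.level3()) == 2
    parents = {}
    for ann in kos.level2():
        assert ann.name in kos.level3_parent  # exactly one parent each
        side = {int(m[1]) % 2 for m in kos.members(ann)}
        assert len(side) == 1
        parents.setdefault(side.pop(), set()).add(kos.level3_parent[ann.name])
    assert parents[0] != parents[1] and all(len(p) == 1 for p in parents.values())


def test_regroup_level3_requires_two_clusters(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {7}, "all")
    table = VectorTable({t: _unit([1, i]) for i, t in enumerate(spec_tree.leaf_terms)}, {})
    with pytest.raises(ValueError):
        regroup_level3(kos, table)


def test_layout_areas_proportional_and_colors(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "A")
    annotate_cluster(kos, {6}, "B")
    table = VectorTable({t: _unit([1, i]) for i, t in enumerate(spec_tree.leaf_terms)}, {})
    regroup_level3(kos, table, n_groups=2)
    records = layout_landscape(kos, table, {"A": 100, "B": 400})
    areas = {r["name"]: r["area"] for r in records}
    assert areas["B"] / areas["A"] == pytest.approx(4.0)
    assert all(np.isfinite([r["x"], r["y"]]).all() for r in records)
    assert len({r["color_key"] for r in records}) == len(kos.level3())
    with pytest.warns(UserWarning, match="no citation"):
        layout_landscape(kos, table, {"A": 1})


def test_newick_export_parses_and_preserves_leaves(spec_tree):
    import dendropy

    nwk = export_tree(spec_tree, "newick")
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"t1", "t2", "t3", "t4"}
    # branch lengths are height differences: leaf t1 sits under node 5 at height 1
    t1 = next(l for l in parsed.leaf_node_iter() if l.taxon.label == "t1")
    assert t1.edge.length == pytest.approx(1.0)
    assert t1.parent_node.edge.length == pytest.approx(10.0 - 1.0)


def test_json_round_trip_identity(spec_tree):
    text = export_tree(spec_tree, "json")
    back = tree_from_json(text)
    assert back == spec_tree
    assert json.loads(export_tree(back, "json")) == json.loads(text)


def test_indented_text_has_one_line_per_node(spec_tree):
    text = export_tree(spec_tree, "indented-text")
    lines = text.strip("\n").split("\n")
    assert len(lines) == 2 * spec_tree.n_leaves - 1
    with pytest.raises(ValueError):
        export_tree(spec_tree, "nexus")


def test_kos_tsv_round_trip(spec_tree):
    kos = KOS(spec_tree)
    annotate_cluster(kos, {5}, "A")
    annotate_cluster(kos, {3, 4}, "B")
    table = VectorTable({t: _unit([1, i]) for i, t in enumerate(spec_tree.leaf_terms)}, {})
    regroup_level3(kos, table, n_groups=2)
    import io, tempfile, os

    with tempfile.TemporaryDirectory() as td:
        path = os.path.join(td, "kos.tsv")
        write_kos_tsv(kos, path)
        back = read_kos_tsv(spec_tree, path)
    assert back.annotations == kos.annotations
    assert back.level3_parent == kos.level3_parent
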