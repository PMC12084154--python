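import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from synstrain.apss import ApssRecord
from synstrain.phylo import (
    edge_list_table,
    export_network,
    rf_distance,
    rf_shuffle_test,
    synteny_distance_matrix,
    upgma_tree,
)


def matrix_from(dists: dict, labels):
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in dists.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def topology(newick: str) -> set:
    """Clades (leaf sets of internal nodes) of a newick via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return {
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_internal_node_iter()
    }


# ---------------------------------------------------------------------------
# distances and UPGMA


def test_synteny_distance_definition():
    recs = [ApssRecord("sp", "A", "B", 40, 50, 0.97, 0)]
    dist = synteny_distance_matrix(recs)
    assert dist.loc["A", "B"] == pytest.approx(0.03)
    assert dist.loc["A", "A"] == 0.0


def test_upgma_two_cherry_topology():
    labels = ["A", "B", "C", "D"]
    mat = matrix_from({("A", "B"): 0.01, ("C", "D"): 0.01,
                       ("A", "C"): 0.2, ("A", "D"): 0.2,
                       ("B", "C"): 0.2, ("B", "D"): 0.2}, labels)
    newick = upgma_tree(mat)
    splits = topology(newick)
    assert frozenset({"A", "B"}) in splits
    assert frozenset({"C", "D"}) in splits


def test_upgma_hand_run_heights():
    # merge (A,B) at h=0.005, (C,D) at 0.005, root at 0.1
    labels = ["A", "B", "C", "D"]
    mat = matrix_from({("A", "B"): 0.01, ("C", "D"): 0.01,
                       ("A", "C"): 0.2, ("A", "D"): 0.2,
                       ("B", "C"): 0.2, ("B", "D"): 0.2}, labels)
    newick = upgma_tree(mat)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    heights = sorted(
        round(n.distance_from_tip(), 6)
        for n in tree.preorder_internal_node_iter()
    )
    assert heights == [0.005, 0.005, 0.1]


def test_upgma_all_equal_distances_deterministic():
    labels = list("ABCD")
    mat = matrix_from({p: 0.1 for p in itertools.combinations(labels, 2)},
                      labels)
    assert upgma_tree(mat) == upgma_tree(mat)


def test_upgma_zero_distance_cherry():
    labels = ["A", "B", "C"]
    mat = matrix_from({("A", "B"): 0.0, ("A", "C"): 0.3, ("B", "C"): 0.3},
                      labels)
    newick = upgma_tree(mat)
    assert "A:0" in newick and "B:0" in newick


def test_upgma_incomplete_matrix_lists_missing():
    mat = matrix_from({("A", "B"): 0.1, ("A", "C"): 0.2}, ["A", "B", "C"])
    mat.loc["B", "C"] = mat.loc["C", "B"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        upgma_tree(mat)


def test_upgma_recovers_random_ultrametric_tree():
    # oracle: build distances from a random ultrametric tree, recover it
    rng = np.random.default_rng(17)
    labels = [f"L{i}" for i in range(8)]

    def random_ultrametric(leaves, height):
        if len(leaves) == 1:
            return leaves[0], {}
        split = rng.integers(1, len(leaves))
        left, dl = random_ultrametric(leaves[:split], height * 0.4)
        right, dr = random_ultrametric(leaves[split:], height * 0.4)
        dists = {**dl, **dr}
        left_leaves = leaves[:split]
        for a in left_leaves:
            for b in leaves[split:]:
                dists[(a, b)] = 2 * height
        return f"({left},{right})", dists

    newick_true, dists = random_ultrametric(labels, 0.5)
    mat = matrix_from(dists, labels)
    recovered = upgma_tree(mat)
    assert topology(recovered) >= topology(newick_true + ";") - {
        frozenset(labels)}


# ---------------------------------------------------------------------------
# Robinson-Foulds


def test_rf_identical_trees_zero():
    t = "((A:1,B:1):1,(C:1,D:1):1);"
    assert rf_distance(t, t) == 0


def test_rf_four_leaf_alternative_topologies():
    a = "((A:1,B:1):1,(C:1,D:1):1);"
    b = "((A:1,C:1):1,(B:1,D:1):1);"
    assert rf_distance(a, b) == 2


def random_binary_newick(labels, rng):
    labels = [str(x) for x in rng.permutation(labels)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:1"
        s = int(rng.integers(1, len(ls)))
        return f"({build(ls[:s])},{build(ls[s:])}):1"

    return build(labels) + ";"


def test_rf_matches_dendropy_oracle():
    rng = np.random.default_rng(3)
    labels = [f"T{i}" for i in range(10)]
    taxa = dendropy.TaxonNamespace(labels)
    for _ in range(10):
        n1 = random_binary_newick(labels, rng)
        n2 = random_binary_newick(labels, rng)
        t1 = dendropy.Tree.get(data=n1, schema="newick",
                               taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=n2, schema="newick",
                               taxon_namespace=taxa)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        oracle = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf_distance(n1, n2) == oracle


def test_rf_metric_properties():
    trees = [
        "((A:1,B:1):1,((C:1,D:1):1,E:1):1);",
        "((A:1,C:1):1,((B:1,D:1):1,E:1):1);",
        "((A:1,E:1):1,((C:1,B:1):1,D:1):1);",
    ]
    for t in trees:
        assert rf_distance(t, t) == 0
    for a, b in itertools.combinations(trees, 2):
        assert rf_distance(a, b) == rf_distance(b, a) >= 0
    for a, b, c in itertools.permutations(trees, 3):
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


def test_shuffle_test_identical_trees_floor_p():
    t = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
    iters = 500
    rf, p = rf_shuffle_test(t, t, iterations=iters, seed=0)
    assert rf == 0
    # only permutations mapping the tree to itself can tie RF=0
    assert p <= 0.5
    assert p >= 1 / (iters + 1)


def test_shuffle_test_mismatched_leaves_rejected():
    with pytest.raises(ValueError):
        rf_shuffle_test("((A:1,B:1):1,C:1);", "((A:1,B:1):1,D:1);",
                        iterations=10)


def test_shuffle_p_valid_under_null():
    # under a label-shuffle null the p-values are valid (superuniform):
    # P(p <= alpha) <= alpha up to Monte-Carlo noise. The RF statistic is
    # heavily discrete on 8 leaves, so exact uniformity is unattainable.
    rng = np.random.default_rng(5)
    base = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    other = "(((A:1,E:1):1,(C:1,G:1):1):1,((B:1,F:1):1,(D:1,H:1):1):1);"
    labels = list("ABCDEFGH")
    pvals = []
    for _ in range(200):
        perm = rng.permutation(labels)
        mapping = dict(zip(labels, perm))
        shuffled = "".join(mapping.get(ch, ch) for ch in base)
        _, p = rf_shuffle_test(shuffled, other, iterations=200,
                               seed=int(rng.integers(2**31)))
        pvals.append(p)
    pvals = np.asarray(pvals)
    for alpha in (0.05, 0.1, 0.2, 0.5):
        assert (pvals <= alpha).mean() <= alpha + 0.07
    assert pvals.min() >= 1 / 201  # add-one smoothing floor


# ---------------------------------------------------------------------------
# networks


def recs_for_network():
    return [
        ApssRecord("sp", "s1", "s2", 40, 50, 1.0, 0),
        ApssRecord("sp", "s1", "s3", 40, 50, 0.75, 0),
        ApssRecord("sp", "s2", "s4", 40, 50, 0.60, 0),  # below cutoff
    ]


METADATA = {
    "s1": {"host": "h1", "country": "X"},
    "s2": {"host": "h2", "country": "X"},
    "s3": {"host": "h3", "country": "Y"},
    "s4": {"host": "h4", "country": "Y"},
}


def test_network_edge_weights():
    g = export_network(recs_for_network(), METADATA)
    assert g["h1"]["h2"]["weight"] == pytest.approx(0.0)
    assert g["h1"]["h3"]["weight"] == pytest.approx(0.1249387366, abs=1e-6)


def test_low_apss_edges_and_singletons_removed():
    g = export_network(recs_for_network(), METADATA)
    assert "h4" not in g  # its only APSS is 0.60 < 0.75
    assert not any(d["apss"] < 0.75 for _, _, d in g.edges(data=True))


def test_missing_host_metadata_rejected():
    with pytest.raises(KeyError):
        export_network(recs_for_network(), {"s1": {"host": "h1"}})


def test_edge_list_round_trip():
    g = export_network(recs_for_network(), METADATA)
    table = edge_list_table(g)
    assert set(table.columns) == {"host_a", "host_b", "apss", "weight"}
    assert len(table) == g.number_of_edges()
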