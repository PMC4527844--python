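"""Tree building: NJ closed forms, additive recovery, consensus rules."""

import dendropy
import numpy as np
import pytest

from granulinkit.distances import DistanceMatrix
from granulinkit.errors import TreeError
from granulinkit.trees import (leaf_distance_matrix, least_squares_refit,
                               majority_rule_consensus, neighbor_joining,
                               read_newick_trees, write_newick)


def _dm(labels, vals):
    return DistanceMatrix(labels, np.asarray(vals, dtype=float), "p")


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick")


def test_three_taxon_closed_form():
    dm = _dm(list("ABC"), [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = neighbor_joining(dm)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_too_few_taxa_rejected():
    with pytest.raises(TreeError):
        neighbor_joining(_dm(["A", "B"], [[0, 1], [1, 0]]))


def test_additive_matrix_recovered_exactly():
    source = _tree("((A:0.11,B:0.23):0.05,((C:0.31,D:0.16):0.07,E:0.09):0.13,F:0.42);")
    pdm = source.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in source.leaf_node_iter())
    tax = {x.label: x for x in source.taxon_namespace}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(
                tax[labels[i]], tax[labels[j]])
    nj = neighbor_joining(_dm(labels, vals))
    back = leaf_distance_matrix(nj)
    idx = [back.labels.index(l) for l in labels]
    assert np.allclose(back.values[np.ix_(idx, idx)], vals, atol=1e-12)


def test_ultrametric_clusters_form_a_bipartition():
    labels = list("ABCDEF")
    vals = np.full((6, 6), 1.0)
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                vals[i, j] = 0.2
    np.fill_diagonal(vals, 0.0)
    nj = neighbor_joining(_dm(labels, vals))
    splits = set()
    for nd in nj.postorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        splits.add(leaves)
        splits.add(frozenset(labels) - leaves)
    assert frozenset("ABC") in splits


def test_least_squares_preserves_additive_lengths():
    source = _tree("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.12,E:0.4);")
    dm = leaf_distance_matrix(source)
    nj = neighbor_joining(dm)
    refit = least_squares_refit(nj, dm)
    assert refit.ls_residual == pytest.approx(0.0, abs=1e-10)
    back = leaf_distance_matrix(refit)
    idx = [back.labels.index(l) for l in dm.labels]
    assert np.allclose(back.values[np.ix_(idx, idx)], dm.values, atol=1e-10)


def test_least_squares_beats_unrefit_lengths_under_noise():
    source = _tree("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.12,E:0.4);")
    dm = leaf_distance_matrix(source)
    rng = np.random.default_rng(0)
    noisy = dm.values + rng.normal(0, 0.01, dm.values.shape)
    noisy = 0.5 * (noisy + noisy.T)
    np.fill_diagonal(noisy, 0.0)
    ndm = DistanceMatrix(dm.labels, noisy, "p")
    refit = least_squares_refit(neighbor_joining(dm), ndm)

    def residual(tree):
        back = leaf_distance_matrix(tree)
        idx = [back.labels.index(l) for l in ndm.labels]
        return float(np.sum((back.values[np.ix_(idx, idx)] - noisy) ** 2)) / 2

    assert residual(refit) <= residual(source) + 1e-12


def test_consensus_of_identical_trees_is_that_topology():
    trees = [_tree("((A,B),(C,D),E);") for _ in range(4)]
    cons = majority_rule_consensus(trees)
    assert set(cons.support_counts.values()) == {4}
    assert len(cons.support_counts) == 2


def test_majority_split_retained_with_support():
    trees = [_tree("((A,B),(C,D),E);"), _tree("((A,B),(C,E),D);"),
             _tree("((A,B),C,(D,E));")]
    cons = majority_rule_consensus(trees)
    sides = {frozenset(s) for s in cons.support_counts}
    # the A|B split is in all three trees (canonical side excludes taxon A)
    assert frozenset("CDE") in sides
    assert cons.support_counts[frozenset("CDE")] == 3


def test_extended_consensus_adds_compatible_minority_splits():
    trees = [_tree("(((A,B),C),D,E);"), _tree("(((A,B),C),E,D);"),
             _tree("((A,(B,C)),D,E);")]
    strict = majority_rule_consensus(trees)
    extended = majority_rule_consensus(trees, extended=True)
    assert len(extended.support_counts) >= len(strict.support_counts)
    # frequency order with first-appearance tie-break is deterministic
    again = majority_rule_consensus(trees, extended=True)
    assert extended.support_counts == again.support_counts


def test_mismatched_leaf_sets_error_names_offender():
    trees = [_tree("((A,B),C,D);"), _tree("((A,B),C,E);")]
    with pytest.raises(TreeError, match="tree 1"):
        majority_rule_consensus(trees)


def test_newick_round_trip(tmp_path):
    dm = _dm(list("ABCD"), [[0, .2, .4, .5], [.2, 0, .45, .55],
                            [.4, .45, 0, .3], [.5, .55, .3, 0]])
    tree = neighbor_joining(dm)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick_trees(path)
    assert len(back) == 1
    assert {lf.taxon.label for lf in back[0].leaf_node_iter()} == set("ABCD")


def test_nj_matches_independent_implementation():
    """Cross-check against scikit-bio's neighbour joining on a random
    (tie-free) matrix: identical split sets."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(12)
    source = _tree("((A:0.2,B:0.4):0.1,((C:0.3,D:0.2):0.2,E:0.5):0.15,F:0.3);")
    dm = leaf_distance_matrix(source)
    noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
    noisy = 0.5 * (noisy + noisy.T)
    np.fill_diagonal(noisy, 0)
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
    mine = neighbor_joining(DistanceMatrix(dm.labels, noisy, "p"))

    def splits(newick_tree):
        t = dendropy.Tree.get(data=newick_tree, schema="newick")
        labs = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        out = set()
        for nd in t.postorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            s = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            out.add(min(s, labs - s, key=sorted))
        return {s for s in out if 1 < len(s) < len(labs) - 1}

    import io
    buf = io.StringIO()
    sk_tree.write(buf)
    assert splits(buf.getvalue()) == splits(mine.as_string(schema="newick"))
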