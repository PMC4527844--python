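"""Distance-based tree inference and consensus.

Neighbor joining with a documented deterministic tie-break, optional
unweighted least-squares branch refitting on a fixed topology, and
(extended) majority-rule consensus of tree sets.  Trees are dendropy
:class:`~dendropy.Tree` objects throughout, so Newick input/output and
interoperation with externally produced tree sets come for free.
"""

from __future__ import annotations

import dendropy
import numpy as np
from scipy.optimize import nnls

from .distances import DistanceMatrix
from .errors import TreeError


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration; exact on additive matrices.

    Ties on the Q criterion break toward the lowest label-index pair, so
    the result is deterministic for a fixed input order.  Negative branch
    length estimates are clamped to zero and recorded on
    ``tree.clamped_edges``.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    clamped = []

    def clamp(x):
        if x < 0:
            clamped.append(round(x, 12))
            return 0.0
        return x

    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        new = dendropy.Node()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            new.add_child(child)
            child.edge.length = ln
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = dendropy.Node()
    for x, ln in ((i, 0.5 * (d[i, j] + d[i, k] - d[j, k])),
                  (j, 0.5 * (d[i, j] + d[j, k] - d[i, k])),
                  (k, 0.5 * (d[i, k] + d[j, k] - d[i, j]))):
        root.add_child(nodes[x])
        nodes[x].edge.length = clamp(ln)
    tree.seed_node = root
    tree.is_rooted = False
    tree.clamped_edges = clamped
    return tree


def leaf_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length distances between all leaf pairs."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            vals[a, b] = vals[b, a] = v
    return DistanceMatrix(labels, vals, "path")


def _edge_crossings(tree: dendropy.Tree, labels: list[str]):
    """For each edge with positive-depth child, the leaf-index set below it."""
    index = {lab: i for i, lab in enumerate(labels)}
    edges, below = [], []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            s = {index[nd.taxon.label]}
        else:
            s = set()
            for ch in nd.child_nodes():
                s |= ch._leafset
        nd._leafset = s
        edges.append(nd.edge)
        below.append(s)
    return edges, below


def least_squares_refit(tree: dendropy.Tree, dm: DistanceMatrix) -> dendropy.Tree:
    """Refit branch lengths by unweighted least squares on path distances.

    Topology is unchanged; negative solutions are excluded by solving the
    non-negative least-squares problem directly.  The residual norm is
    stored on ``tree.ls_residual``.
    """
    tree = tree.clone(depth=1)
    tree_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_labels != set(dm.labels):
        raise TreeError("tree leaves do not match matrix labels")
    labels = dm.labels
    edges, below = _edge_crossings(tree, labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    a = np.zeros((len(pairs), len(edges)))
    y = np.array([dm.values[i, j] for i, j in pairs])
    for e, s in enumerate(below):
        for p, (i, j) in enumerate(pairs):
            if (i in s) != (j in s):
                a[p, e] = 1.0
    x, residual = nnls(a, y)
    if np.linalg.matrix_rank(a) < a.shape[1]:
        tree.singular_design = True
    for e, edge in enumerate(edges):
        edge.length = float(x[e])
    tree.ls_residual = float(residual)
    return tree


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree, leaf_set: frozenset[str]):
    """Non-trivial bipartitions as frozensets of the side excluding the
    reference (lexicographically smallest) taxon."""
    ref = min(leaf_set)
    out = []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            nd._side = frozenset([nd.taxon.label])
            continue
        side = frozenset().union(*(ch._side for ch in nd.child_nodes()))
        nd._side = side
        canon = side if ref not in side else leaf_set - side
        if 1 < len(canon) < len(leaf_set) - 1:
            out.append(canon)
    return out


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def majority_rule_consensus(trees: list[dendropy.Tree],
                            extended: bool = False) -> dendropy.Tree:
    """(Extended) majority-rule consensus of trees on one leaf set.

    Bipartitions present in more than half of the trees are retained; with
    ``extended`` the remaining compatible bipartitions are added greedily in
    frequency order (ties: first appearance).  Each retained split carries
    its support count as the internal node label.
    """
    if not trees:
        raise TreeError("no input trees")
    leaf_sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                 for t in trees]
    leaf_set = leaf_sets[0]
    for k, ls in enumerate(leaf_sets):
        if ls != leaf_set:
            raise TreeError(
                f"tree {k} leaf set differs from the first "
                f"(+{sorted(ls - leaf_set)} -{sorted(leaf_set - ls)})"
            )
    counts: dict[frozenset, int] = {}
    order: dict[frozenset, int] = {}
    for t in trees:
        for s in set(_splits(t, leaf_set)):
            counts[s] = counts.get(s, 0) + 1
            order.setdefault(s, len(order))
    majority = [s for s, c in counts.items() if 2 * c > len(trees)]
    accepted = sorted(majority, key=lambda s: order[s])
    if extended:
        rest = sorted((s for s in counts if s not in set(majority)),
                      key=lambda s: (-counts[s], order[s]))
        for s in rest:
            if all(_compatible(s, t) for t in accepted):
                accepted.append(s)

    # build the rooted-at-reference representation from nested splits
    tns = dendropy.TaxonNamespace(sorted(leaf_set))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    leaf_nodes = {}
    for lab in sorted(leaf_set):
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        leaf_nodes[lab] = nd
        root.add_child(nd)
    for s in sorted(accepted, key=len, reverse=True):
        # deepest current node containing every leaf of s among its children
        host = root
        while True:
            nxt = None
            for ch in host.child_nodes():
                if not ch.is_leaf() and s <= ch._group:
                    nxt = ch
                    break
            if nxt is None:
                break
            host = nxt
        members = [ch for ch in host.child_nodes()
                   if (ch._group if not ch.is_leaf()
                       else frozenset([ch.taxon.label])) <= s]
        grp = dendropy.Node()
        grp.label = str(counts[s])
        grp._group = s
        for ch in members:
            host.remove_child(ch)
            grp.add_child(ch)
        host.add_child(grp)
    tree.seed_node = root
    tree.is_rooted = False
    tree.support_counts = {s: counts[s] for s in accepted}
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_newick_trees(path) -> list[dendropy.Tree]:
    """Read a newline-delimited multi-tree Newick file (the import hook for
    externally produced tree sets)."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(tl)
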