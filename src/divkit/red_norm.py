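"""Relative evolutionary divergence (RED) and rank-normalized trees.

RED interpolates a node statistic from 0 at the root to 1 at every leaf:

    red(n) = red(p) + (d / u) * (1 - red(p))

where ``d`` is the branch length from parent ``p`` to ``n`` and ``u`` is
``d`` plus the mean path length from ``n`` to its descendant leaves.  On an
ultrametric tree this reduces to depth(n) / total depth.

The rank-normalized tree keeps the topology and replaces every branch length
with red(child) - red(parent); all root-to-leaf paths then sum to exactly 1,
which removes lineage-specific rate differences before diversity summaries.
"""

from __future__ import annotations

import dendropy

from .treekit import assign_node_ids

__all__ = ["compute_red", "rank_normalize_tree"]


def compute_red(tree: dendropy.Tree) -> dict[str, float]:
    """RED value for every node, keyed by ``node_id``.

    The root gets 0, every leaf exactly 1.  Any stem length on the root is
    ignored.  Degenerate zero-length subtrees inherit the parent's RED.
    Values are clamped to [red(parent), 1] so the table invariants hold under
    floating-point rounding.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    if not hasattr(tree.seed_node, "node_id"):
        assign_node_ids(tree)

    # postorder: mean distance from each node down to its descendant leaves
    mean_leaf_dist: dict[dendropy.Node, float] = {}
    n_leaves: dict[dendropy.Node, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            mean_leaf_dist[nd], n_leaves[nd] = 0.0, 1
        else:
            total, count = 0.0, 0
            for c in nd.child_nodes():
                bl = c.edge.length or 0.0
                total += (mean_leaf_dist[c] + bl) * n_leaves[c]
                count += n_leaves[c]
            mean_leaf_dist[nd] = total / count
            n_leaves[nd] = count

    red: dict[str, float] = {}
    red_node: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    red[tree.seed_node.node_id] = 0.0
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        rp = red_node[nd.parent_node]
        if nd.is_leaf():
            r = 1.0
        else:
            d = nd.edge.length or 0.0
            u = d + mean_leaf_dist[nd]
            r = rp if u == 0.0 else rp + (d / u) * (1.0 - rp)
            r = min(max(r, rp), 1.0)
        red_node[nd] = r
        red[nd.node_id] = r
    return red


def rank_normalize_tree(tree: dendropy.Tree, red: dict[str, float]) -> dendropy.Tree:
    """Clone ``tree`` with branch lengths replaced by RED differences.

    The returned tree is ultrametric with every root-to-leaf path summing to
    1 (telescoping red(leaf) - red(root) = 1 - 0).  Node ids, supports and
    taxon labels carry over; the input tree is left untouched.
    """
    def clone(nd: dendropy.Node, parent_red: float | None) -> dendropy.Node:
        new = dendropy.Node()
        if nd.taxon is not None:
            new.taxon = nd.taxon
        new.node_id = nd.node_id
        new.support = getattr(nd, "support", None)
        new.taxon_labels = list(getattr(nd, "taxon_labels", []) or [])
        try:
            r = red[nd.node_id]
        except KeyError:
            raise ValueError(f"RED table missing node {nd.node_id!r}") from None
        new.edge.length = None if parent_red is None else r - parent_red
        for c in nd.child_nodes():
            new.add_child(clone(c, r))
        return new

    out = dendropy.Tree(taxon_namespace=tree.taxon_namespace)
    out.seed_node = clone(tree.seed_node, None)
    return out
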