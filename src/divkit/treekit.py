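"""Rooted Newick trees in the GTDB label dialect, and taxonomic decoration.

GTDB release trees carry internal-node labels of the form ``'support:taxon'``
(quoted because of the colon), where the taxon part may itself list several
rank-prefixed names separated by ``"; "`` — e.g. ``'100.0:p__Patescibacteriota;
c__ABY1'``.  This module reads and writes that dialect losslessly and places
taxon labels on nodes by maximising the F-measure between a node's
descendant-leaf set and the taxon's member-leaf set, the criterion used by
rank-decoration tools in this field.

Trees are represented as :class:`dendropy.Tree` objects; every node
additionally carries

``node_id``
    a stable identifier: the leaf name for leaves, ``"N<k>"`` (preorder
    index) for internal nodes;
``support``
    optional float parsed from the label;
``taxon_labels``
    list of rank-prefixed names parsed from the label.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_SYMBOLS = "dpcofgs"
RANK_NAMES = {
    "d": "domain", "p": "phylum", "c": "class", "o": "order",
    "f": "family", "g": "genus", "s": "species",
}
_RANK_FROM_NAME = {v: k for k, v in RANK_NAMES.items()}

#: characters that force quoting when writing a Newick label
_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`<>^]")


class TreeParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate leaves, ...)."""


def normalize_rank(rank: str) -> str:
    """Return the one-letter rank symbol for ``rank`` ('p', 'phylum', 'p__')."""
    r = rank.rstrip("_").lower()
    if r in RANK_NAMES:
        return r
    if r in _RANK_FROM_NAME:
        return _RANK_FROM_NAME[r]
    raise ValueError(f"unknown rank symbol {rank!r}; expected one of d,p,c,o,f,g,s")


def rank_index(rank: str) -> int:
    return RANK_SYMBOLS.index(normalize_rank(rank))


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _split_compound_label(label: str | None) -> tuple[float | None, list[str]]:
    """Split a GTDB internal-node label into (support, taxon_labels).

    The first ':' inside the (already unquoted) label separates support from
    the taxon list; multiple taxa are separated by ';'.  A bare number is a
    support; a bare name is a taxon.
    """
    if label is None or label == "":
        return None, []
    if ":" in label:
        left, right = label.split(":", 1)
        try:
            support = float(left)
        except ValueError:
            support, right = None, label
        taxa = [t.strip() for t in right.split(";") if t.strip()]
        return support, taxa
    try:
        return float(label), []
    except ValueError:
        return None, [t.strip() for t in label.split(";") if t.strip()]


def _join_compound_label(support: float | None, taxa: list[str]) -> str | None:
    if support is None and not taxa:
        return None
    if support is None:
        return "; ".join(taxa)
    if not taxa:
        return repr(support)
    return f"{support!r}:{'; '.join(taxa)}"


def assign_node_ids(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Assign stable ``node_id`` attributes (preorder) and return id → node."""
    index: dict[str, dendropy.Node] = {}
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.node_id = nd.taxon.label if nd.taxon else f"L{k}"
        else:
            nd.node_id = f"N{k}"
        if nd.node_id in index:
            raise TreeParseError(f"duplicate leaf name {nd.node_id!r}")
        index[nd.node_id] = nd
        k += 1
    return index


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string in the GTDB dialect into a rooted dendropy tree.

    Supports and taxon labels are split out of compound internal labels into
    ``node.support`` and ``node.taxon_labels``.  Branch lengths are preserved
    at full precision; a missing branch length is treated as 0 (warned).
    Raises :class:`TreeParseError` on malformed input, duplicate leaf names
    or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several dataio error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc

    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and nd.edge.length < 0:
            who = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
            raise TreeParseError(
                f"negative branch length {nd.edge.length} at node {who!r}"
            )
        if nd.parent_node is not None and nd.edge.length is None:
            logger.warning("node missing branch length; treating as 0")
            nd.edge.length = 0.0
        nd.support, nd.taxon_labels = _split_compound_label(
            nd.label if not nd.is_leaf() else None
        )
    assign_node_ids(tree)
    return tree


def _format_label(raw: str) -> str:
    if raw == "" or _NEEDS_QUOTE.search(raw):
        return "'" + raw.replace("'", "''") + "'"
    return raw


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree back to the GTDB Newick dialect.

    Branch lengths use shortest-round-trip float formatting, so
    ``parse_newick(write_newick(t))`` reproduces them exactly.
    """

    def emit(nd: dendropy.Node) -> str:
        if nd.is_leaf():
            body = _format_label(nd.taxon.label if nd.taxon else "")
        else:
            inner = ",".join(emit(c) for c in nd.child_nodes())
            label = _join_compound_label(
                getattr(nd, "support", None), getattr(nd, "taxon_labels", [])
            )
            body = f"({inner})" + (_format_label(label) if label else "")
        if nd.edge.length is not None:
            body += f":{nd.edge.length!r}"
        return body

    return emit(tree.seed_node) + ";"


def read_tree(path: str) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_tree(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# taxonomy maps
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> list[str]:
    """Split ``"d__X;p__Y;..."`` into its 7 rank-prefixed names, validated."""
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != 7:
        raise ValueError(f"expected 7 ranks, got {len(parts)}: {lineage!r}")
    for i, p in enumerate(parts):
        if not p.startswith(RANK_PREFIXES[i]):
            raise ValueError(
                f"rank {i} entry {p!r} does not start with {RANK_PREFIXES[i]!r}"
            )
    return parts


def read_taxonomy(path: str) -> dict[str, list[str]]:
    """Read a 2-column TSV (leaf_id, semicolon-joined 7-rank lineage)."""
    taxonomy: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            leaf, lineage = line.split("\t", 1)
            if leaf in taxonomy:
                raise ValueError(f"leaf {leaf!r} appears twice in taxonomy")
            taxonomy[leaf] = parse_lineage(lineage)
    return taxonomy


def write_taxonomy(taxonomy: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for leaf, lineage in taxonomy.items():
            fh.write(f"{leaf}\t{';'.join(lineage)}\n")


# ---------------------------------------------------------------------------
# decoration
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """Where one taxon landed on the tree."""

    taxon: str
    node: dendropy.Node
    fmeasure: float
    n_leaves: int
    singleton: bool


@dataclass
class DecoratedTree:
    """A tree plus one placement per taxon at a given rank."""

    tree: dendropy.Tree
    rank: str
    placements: dict[str, Placement] = field(default_factory=dict)

    @property
    def fmeasures(self) -> dict[str, float]:
        return {t: p.fmeasure for t, p in self.placements.items()}

    def report(self):
        """Placement report as a pandas DataFrame (taxon, node, fmeasure, ...)."""
        import pandas as pd

        rows = [
            {
                "taxon": p.taxon,
                "node": p.node.node_id,
                "fmeasure": p.fmeasure,
                "n_leaves": p.n_leaves,
                "singleton": p.singleton,
            }
            for p in sorted(self.placements.values(), key=lambda p: p.taxon)
        ]
        return pd.DataFrame(rows, columns=["taxon", "node", "fmeasure", "n_leaves", "singleton"])


def _min_leaf_name(nd: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in nd.leaf_iter())


def decorate(tree: dendropy.Tree, taxonomy: dict[str, list[str]], rank: str) -> DecoratedTree:
    """Place every taxon at ``rank`` on its best-matching node.

    For a taxon with member-leaf set S, each node with descendant-leaf set L
    scores F = 2PR/(P+R), P = |L∩S|/|L|, R = |L∩S|/|S|.  The argmax node wins;
    ties break by fewer descendant leaves, then smaller depth from the root,
    then lexicographically smallest descendant leaf name.  A taxon with a
    single member leaf is placed on that leaf and flagged singleton.

    Leaves absent from ``taxonomy`` are skipped with a warning.  The winning
    taxon label is appended to the node's ``taxon_labels``.
    """
    if not taxonomy:
        raise ValueError("empty taxonomy")
    ri = rank_index(rank)

    members: dict[str, set[str]] = {}
    for lf in tree.leaf_node_iter():
        name = lf.taxon.label
        lineage = taxonomy.get(name)
        if lineage is None:
            logger.warning("leaf %r missing from taxonomy; skipped", name)
            continue
        taxon = lineage[ri]
        if taxon[3:]:  # skip rank left unassigned ("p__")
            members.setdefault(taxon, set()).add(name)

    # per-node bookkeeping in one postorder pass
    n_desc: dict[dendropy.Node, int] = {}
    for nd in tree.postorder_node_iter():
        n_desc[nd] = 1 if nd.is_leaf() else sum(n_desc[c] for c in nd.child_nodes())
    depth = {tree.seed_node: 0}
    for nd in tree.preorder_node_iter():
        for c in nd.child_nodes():
            depth[c] = depth[nd] + 1

    decorated = DecoratedTree(tree=tree, rank=normalize_rank(rank))
    for taxon in sorted(members):
        S = members[taxon]
        if len(S) == 1:
            leaf = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label in S
            )
            leaf.taxon_labels = sorted(set(getattr(leaf, "taxon_labels", []) or []) | {taxon})
            decorated.placements[taxon] = Placement(taxon, leaf, 1.0, 1, True)
            continue

        # count of member leaves under each node, postorder
        hits: dict[dendropy.Node, int] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                hits[nd] = 1 if nd.taxon.label in S else 0
            else:
                hits[nd] = sum(hits[c] for c in nd.child_nodes())

        best: tuple | None = None
        best_node = None
        for nd in tree.preorder_node_iter():
            h = hits[nd]
            if h == 0:
                continue
            precision = h / n_desc[nd]
            recall = h / len(S)
            f = 2 * precision * recall / (precision + recall)
            key = (-f, n_desc[nd], depth[nd], _min_leaf_name(nd))
            if best is None or key < best:
                best, best_node = key, nd
        assert best_node is not None
        best_node.taxon_labels = sorted(
            set(getattr(best_node, "taxon_labels", []) or []) | {taxon}
        )
        decorated.placements[taxon] = Placement(
            taxon, best_node, -best[0], len(S), False
        )
    return decorated
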