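"""Per-taxon phylogenetic diversity (PD) profiles.

For a taxon anchored at node ``v``, PD is the sum of every branch length
inside the subtree rooted at ``v`` plus the stem branch of ``v`` itself.  A
singleton taxon (one member leaf, no named internal node) contributes just
its leaf's stem.  A profile normalises these per-taxon sums by their total
over all taxa at the rank — named and singleton alike — giving each taxon a
fraction of the tracked evolutionary history, and ranks taxa by that
fraction (dense ranking, ties broken lexicographically).

The *adjusted* profile runs the identical computation on the rank-normalized
(RED-scaled) tree, using placements found on the original tree, which
down-weights clades whose apparent diversity is inflated by fast
evolutionary rates.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import dendropy
import pandas as pd

from .red_norm import compute_red, rank_normalize_tree
from .treekit import DecoratedTree, decorate

logger = logging.getLogger(__name__)

#: GTDB polyphyly suffix, e.g. "p__Bacillota_A" -> base "p__Bacillota"
_POLYPHYLY_SUFFIX = re.compile(r"_[A-Z]+$")

PROFILE_COLUMNS = ["taxon", "node", "n_leaves", "singleton", "pd_raw", "pd_fraction", "rank_position"]


@dataclass
class PDRecord:
    taxon: str
    node_id: str
    n_leaves: int
    is_singleton: bool
    pd_raw: float
    pd_fraction: float = math.nan
    rank_position: int = 0


def taxon_pd(tree: dendropy.Tree, node: dendropy.Node) -> float:
    """Subtree branch-length sum plus the node's own stem.

    For a leaf this is the stem length alone (the singleton rule).  The root
    has no stem; its contribution is 0 (logged).
    """
    if node.parent_node is None:
        logger.info("taxon_pd at the root: no stem, using subtree sum only")
        stem = 0.0
    else:
        stem = node.edge.length or 0.0
    subtree = sum(
        (nd.edge.length or 0.0)
        for nd in node.preorder_iter()
        if nd is not node
    )
    return subtree + stem


def _records_from_decoration(decorated: DecoratedTree, tree: dendropy.Tree | None = None) -> list[PDRecord]:
    """Raw PD per placed taxon, optionally measured on a different (rescaled)
    tree that shares node ids with the decorated one."""
    node_by_id = None
    if tree is not None:
        node_by_id = {nd.node_id: nd for nd in tree.preorder_node_iter()}
    records = []
    for p in decorated.placements.values():
        if node_by_id is None:
            target_tree, node = decorated.tree, p.node
        else:
            target_tree, node = tree, node_by_id[p.node.node_id]
        records.append(
            PDRecord(
                taxon=p.taxon,
                node_id=p.node.node_id,
                n_leaves=p.n_leaves,
                is_singleton=p.singleton,
                pd_raw=taxon_pd(target_tree, node),
            )
        )
    return records


def _consolidate(records: list[PDRecord]) -> list[PDRecord]:
    """Merge taxa differing only by a polyphyly suffix, summing pd_raw."""
    prefix = lambda t: t[:3]
    base = lambda t: prefix(t) + _POLYPHYLY_SUFFIX.sub("", t[3:])
    groups: dict[str, list[PDRecord]] = {}
    for r in records:
        groups.setdefault(base(r.taxon), []).append(r)
    merged = []
    for name, rs in groups.items():
        if len(rs) == 1 and rs[0].taxon == name:
            merged.append(rs[0])
            continue
        rs.sort(key=lambda r: r.taxon)
        merged.append(
            PDRecord(
                taxon=name,
                node_id=rs[0].node_id,
                n_leaves=sum(r.n_leaves for r in rs),
                is_singleton=all(r.is_singleton for r in rs) and len(rs) == 1,
                pd_raw=math.fsum(r.pd_raw for r in rs),
            )
        )
    return merged


def _finalize(records: list[PDRecord]) -> list[PDRecord]:
    total = math.fsum(r.pd_raw for r in records)
    if total <= 0:
        raise ValueError("degenerate tree: total PD is zero")
    for r in records:
        r.pd_fraction = r.pd_raw / total
    records.sort(key=lambda r: (-r.pd_fraction, r.taxon))
    pos, prev = 0, None
    for r in records:
        if r.pd_fraction != prev:
            pos += 1
            prev = r.pd_fraction
        r.rank_position = pos
    return records


def pd_profile(decorated: DecoratedTree, consolidate: bool = False) -> list[PDRecord]:
    """PD profile over all taxa placed at the decoration's rank.

    Fractions are pd_raw / Σ pd_raw (named and singleton taxa both enter the
    denominator) and sum to 1; records come back sorted by descending
    fraction with dense rank positions.  With ``consolidate=True``, taxa
    whose names differ only by a GTDB polyphyly suffix (``_A``, ``_B``...)
    are merged — pd_raw summed — before normalisation and ranking.
    """
    if not decorated.placements:
        raise ValueError("decoration holds no placements")
    records = _records_from_decoration(decorated)
    if consolidate:
        records = _consolidate(records)
    return _finalize(records)


def adjusted_pd_profile(
    tree: dendropy.Tree,
    taxonomy: dict[str, list[str]],
    rank: str,
    consolidate: bool = False,
) -> list[PDRecord]:
    """PD profile measured on the rank-normalized tree.

    Placements are computed once on the original tree and carried over; stems
    and subtree sums are then measured in RED units.
    """
    decorated = decorate(tree, taxonomy, rank)
    scaled = rank_normalize_tree(tree, compute_red(tree))
    records = _records_from_decoration(decorated, tree=scaled)
    if consolidate:
        records = _consolidate(records)
    return _finalize(records)


def profile_frame(records: list[PDRecord]) -> pd.DataFrame:
    """Profile as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "node": r.node_id,
                "n_leaves": r.n_leaves,
                "singleton": r.is_singleton,
                "pd_raw": r.pd_raw,
                "pd_fraction": r.pd_fraction,
                "rank_position": r.rank_position,
            }
            for r in records
        ],
        columns=PROFILE_COLUMNS,
    )


def compare_rankings(standard: list[PDRecord], adjusted: list[PDRecord]) -> pd.DataFrame:
    """Side-by-side table of standard vs adjusted fractions and ranks.

    Full outer join on taxon; taxa present in only one profile get NaN on the
    missing side and are flagged.  ``delta`` = adj_rank - std_rank (positive
    means the taxon dropped after rate adjustment).
    """
    if not standard or not adjusted:
        raise ValueError("both profiles must be non-empty")
    std = pd.DataFrame(
        {"taxon": [r.taxon for r in standard],
         "std_fraction": [r.pd_fraction for r in standard],
         "std_rank": [r.rank_position for r in standard]}
    )
    adj = pd.DataFrame(
        {"taxon": [r.taxon for r in adjusted],
         "adj_fraction": [r.pd_fraction for r in adjusted],
         "adj_rank": [r.rank_position for r in adjusted]}
    )
    out = std.merge(adj, on="taxon", how="outer")
    out["delta"] = out["adj_rank"] - out["std_rank"]
    out["missing"] = out["std_rank"].isna() | out["adj_rank"].isna()
    return out.sort_values("taxon", ignore_index=True)[
        ["taxon", "std_fraction", "adj_fraction", "std_rank", "adj_rank", "delta", "missing"]
    ]
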