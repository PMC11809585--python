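"""Seeded generators for trees, taxonomies and genomes.

These generators produce inputs with the statistical structure the rest of
the package assumes — planted monophyletic taxa at all seven ranks
(including singleton phyla and clades with inflated branch-length rates),
genome pairs at controlled substitution divergence and GC content, and
genomes with planted CDS intervals and marker-gene insertions — together
with ground-truth bookkeeping, so every pipeline stage can be verified
end-to-end without downloads.

Every generator is a pure function of its spec: the same spec yields
byte-identical output.  All randomness flows from one
``numpy.random.default_rng(seed)`` instance per call.

Trees come from a timed pure-birth (Yule) process, one subtree per phylum,
joined under a common root; monophyly of every planted taxon is therefore
guaranteed by construction.  Ranks below phylum follow the subtree's own
nesting: the children of a phylum's crown node anchor its classes, their
children the orders, and so on down to genus, with leaf lineages padded when
a branch bottoms out early; species are one per leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genomestats import GenomeRecord, Insert, InsertMap
from .treekit import RANK_PREFIXES, assign_node_ids

__all__ = [
    "TreeSimSpec", "GenomeSimSpec", "SimulatedTree", "TruthRecord",
    "SimulatedAnnotatedGenome", "simulate_tree", "simulate_genome_pair",
    "simulate_annotated_genome",
]

_GENUS_IDX = 5  # d p c o f g s → genus is index 5
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSimSpec:
    """Plan for one simulated decorated tree.

    ``rate_inflation`` multiplies every branch strictly inside the named
    phylum's crown subtree, emulating a clade shaped by fast evolutionary
    rates.  ``ultrametric`` keeps the timed process depths (every leaf at
    depth 1); otherwise each branch gets independent lognormal rate jitter.
    """

    n_leaves: int
    n_phyla: int = 3
    n_singleton_phyla: int = 0
    seed: int = 0
    ultrametric: bool = False
    birth_rate: float = 1.0
    rate_jitter_sigma: float = 0.6
    rate_inflation: tuple[str, float] | None = None

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if not 0 <= self.n_singleton_phyla <= self.n_phyla:
            raise ValueError("singleton phyla must be a subset of phyla")
        needed = 2 * (self.n_phyla - self.n_singleton_phyla) + self.n_singleton_phyla
        if needed > self.n_leaves or self.n_phyla < 1:
            raise ValueError(
                f"taxonomy plan needs {needed} leaves for {self.n_phyla} phyla "
                f"but only {self.n_leaves} requested"
            )


@dataclass(frozen=True)
class GenomeSimSpec:
    """Plan for simulated genome sequence(s).

    ``divergence`` is the fraction of sites substituted (always to a
    different base, so it equals the observed mismatch fraction exactly).
    ``cds_plan`` / ``insert_plan`` are 1-based inclusive (start, length)
    tuples.
    """

    length_bp: int
    gc_target: float = 0.5
    divergence: float = 0.0
    seed: int = 0
    cds_plan: tuple[tuple[int, int], ...] | None = None
    insert_plan: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0,1)")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0,1)")


@dataclass
class TruthRecord:
    taxon: str
    rank: str  # one-letter symbol
    node_id: str
    pd_raw: float
    n_leaves: int
    singleton: bool


@dataclass
class SimulatedTree:
    tree: dendropy.Tree
    taxonomy: dict[str, list[str]]
    truth: list[TruthRecord] = field(default_factory=list)

    def truth_at_rank(self, rank_symbol: str) -> dict[str, TruthRecord]:
        return {t.taxon: t for t in self.truth if t.rank == rank_symbol}


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _yule_subtree(leaf_names: list[str], rng: np.random.Generator, birth_rate: float):
    """Timed pure-birth subtree over the given leaves; returns (crown, depth).

    Lineages split at exponential waiting times; all tips are extended to the
    final time so the subtree is ultrametric with the returned crown depth.
    """
    crown = dendropy.Node()
    tips: list[tuple[dendropy.Node, float]] = [(crown, 0.0)]
    t = 0.0
    while len(tips) < len(leaf_names):
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = int(rng.integers(len(tips)))
        nd, _birth = tips.pop(i)
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            tips.append((child, t))
        # internal edge length fixed once both endpoints known
        nd._split_time = t
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    crown._birth_time = 0.0
    for nd in crown.preorder_iter():
        for c in nd.child_nodes():
            c._birth_time = nd._split_time
    for nd in crown.preorder_iter():
        if nd is crown:
            continue
        end = getattr(nd, "_split_time", t_end)
        nd.edge.length = end - nd._birth_time
    # label leaves in tree (preorder) traversal order for determinism
    for leaf, name in zip(crown.leaf_iter(), leaf_names):
        leaf.taxon = dendropy.Taxon(label=name)
    # crown depth runs from the first split, not from process time 0
    return crown, t_end - crown._split_time


def _scale_subtree(node: dendropy.Node, factor: float) -> None:
    for nd in node.preorder_iter():
        if nd is not node and nd.edge.length is not None:
            nd.edge.length *= factor


def simulate_tree(spec: TreeSimSpec) -> SimulatedTree:
    """Simulate a rooted tree with a planted 7-rank taxonomy and PD truth.

    Returns the tree (node ids assigned), a full 7-rank lineage for every
    leaf, and one :class:`TruthRecord` per planted taxon carrying its anchor
    node and exact raw PD (subtree branch sum plus stem) measured on the
    final branch lengths.
    """
    rng = np.random.default_rng(spec.seed)
    n_named = spec.n_phyla - spec.n_singleton_phyla

    # leaf allotment: named phyla get >=2 leaves, singletons exactly 1
    counts = np.full(spec.n_phyla, 1, dtype=int)
    counts[:n_named] = 2
    spare = spec.n_leaves - counts.sum()
    if spare and n_named:
        extra = rng.multinomial(spare, np.full(n_named, 1.0 / n_named))
        counts[:n_named] += extra
    elif spare:
        counts[0] += spare

    width = len(str(spec.n_leaves))
    leaf_iterator = iter(f"L{i:0{width}d}" for i in range(1, spec.n_leaves + 1))

    root = dendropy.Node()
    phylum_nodes: dict[str, dendropy.Node] = {}
    for i, m in enumerate(counts, start=1):
        name = f"p__P{i}"
        if m == 1:
            leaf = dendropy.Node(taxon=dendropy.Taxon(label=next(leaf_iterator)))
            root.add_child(leaf)
            leaf.edge.length = 1.0 if spec.ultrametric else rng.exponential(0.5)
            phylum_nodes[name] = leaf
        else:
            names = [next(leaf_iterator) for _ in range(m)]
            crown, depth = _yule_subtree(names, rng, spec.birth_rate)
            crown_depth = rng.uniform(0.3, 0.8)
            _scale_subtree(crown, crown_depth / depth)
            root.add_child(crown)
            crown.edge.length = (
                1.0 - crown_depth if spec.ultrametric else rng.exponential(0.3)
            )
            phylum_nodes[name] = crown

    tree = dendropy.Tree()
    tree.seed_node = root
    ns = dendropy.TaxonNamespace(
        [lf.taxon for lf in tree.leaf_node_iter()]
    )
    tree.taxon_namespace = ns

    if not spec.ultrametric:
        for nd in tree.preorder_node_iter():
            if nd is not root and nd.edge.length is not None:
                nd.edge.length *= rng.lognormal(0.0, spec.rate_jitter_sigma)

    # plant ranks below phylum by subtree nesting
    for nd in tree.preorder_node_iter():
        nd.support, nd.taxon_labels = None, []
    planted: list[tuple[str, int, dendropy.Node]] = []

    def plant(node: dendropy.Node, rank_idx: int, base: str) -> None:
        planted.append((RANK_PREFIXES[rank_idx] + base, rank_idx, node))
        if rank_idx >= _GENUS_IDX:
            return
        if node.is_leaf():
            for r in range(rank_idx + 1, _GENUS_IDX + 1):
                planted.append((RANK_PREFIXES[r] + base, r, node))
            return
        for j, child in enumerate(node.child_nodes()):
            plant(child, rank_idx + 1, base + chr(ord("a") + j))

    for i, (name, node) in enumerate(phylum_nodes.items(), start=1):
        plant(node, 1, f"P{i}")

    # apply rate inflation after planting, before truth bookkeeping
    if spec.rate_inflation is not None:
        target, mult = spec.rate_inflation
        if target not in phylum_nodes:
            raise ValueError(f"rate_inflation names unknown phylum {target!r}")
        _scale_subtree(phylum_nodes[target], mult)

    assign_node_ids(tree)

    # lineages
    taxonomy = {
        lf.taxon.label: ["d__Bacteria"] + [""] * 5 + [f"s__{lf.taxon.label}"]
        for lf in tree.leaf_node_iter()
    }
    for name, rank_idx, node in planted:
        for lf in node.leaf_iter():
            taxonomy[lf.taxon.label][rank_idx] = name

    # truth: subtree sums bottom-up (generator bookkeeping), plus stems
    subtree_sum: dict[dendropy.Node, float] = {}
    leaf_count: dict[dendropy.Node, int] = {}
    for nd in tree.postorder_node_iter():
        kids = nd.child_nodes()
        leaf_count[nd] = 1 if not kids else sum(leaf_count[c] for c in kids)
        subtree_sum[nd] = sum(
            subtree_sum[c] + (c.edge.length or 0.0) for c in kids
        )
    truth = [
        TruthRecord(
            taxon=name,
            rank=RANK_PREFIXES[rank_idx][0],
            node_id=node.node_id,
            pd_raw=subtree_sum[node] + (node.edge.length or 0.0),
            n_leaves=leaf_count[node],
            singleton=node.is_leaf(),
        )
        for name, rank_idx, node in planted
    ]
    truth.extend(
        TruthRecord(
            taxon=f"s__{lf.taxon.label}",
            rank="s",
            node_id=lf.node_id,
            pd_raw=lf.edge.length or 0.0,
            n_leaves=1,
            singleton=True,
        )
        for lf in tree.leaf_node_iter()
    )
    return SimulatedTree(tree=tree, taxonomy=taxonomy, truth=truth)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def simulate_genome_pair(spec: GenomeSimSpec):
    """(genome A, genome B, true substitution count).

    B is a copy of A with ``round(divergence × length)`` substitutions at
    distinct uniformly chosen sites, each to a different base, so the
    realized mismatch fraction equals the returned count / length exactly.
    """
    rng = np.random.default_rng(spec.seed)
    a = _random_sequence(rng, spec.length_bp, spec.gc_target)
    b = a.copy()
    n_sub = int(round(spec.divergence * spec.length_bp))
    if n_sub:
        sites = rng.choice(spec.length_bp, size=n_sub, replace=False)
        # shift each base by 1..3 in A,C,G,T order: never the original base
        idx = np.searchsorted(_BASES, b[sites])
        shift = rng.integers(1, 4, size=n_sub)
        b[sites] = _BASES[(idx + shift) % 4]
    rec_a = GenomeRecord(f"sim{spec.seed}A", [("contig1", a.tobytes().decode())])
    rec_b = GenomeRecord(f"sim{spec.seed}B", [("contig1", b.tobytes().decode())])
    return rec_a, rec_b, n_sub


@dataclass
class SimulatedAnnotatedGenome:
    record: GenomeRecord
    gff3: str
    insert_map: InsertMap | None
    coding_density_truth: float | None


def simulate_annotated_genome(spec: GenomeSimSpec) -> SimulatedAnnotatedGenome:
    """Genome with planted CDS features and marker-gene insertions.

    The GFF3 carries one CDS feature per ``cds_plan`` interval; the
    ``insert_map`` ground truth replays ``insert_plan`` as gene-local
    insert-inclusive coordinates.  The coding-density truth is computed by an
    independent per-base coverage mask.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_sequence(rng, spec.length_bp, spec.gc_target).tobytes().decode()
    record = GenomeRecord(f"sim{spec.seed}", [("contig1", seq)])

    lines = ["##gff-version 3"]
    density = None
    if spec.cds_plan is not None:
        mask = np.zeros(spec.length_bp, dtype=bool)
        for k, (start, length) in enumerate(spec.cds_plan, start=1):
            end = start + length - 1
            if start < 1 or end > spec.length_bp:
                raise ValueError(f"CDS interval ({start},{length}) outside genome")
            mask[start - 1: end] = True
            lines.append(
                f"contig1\tdivkit_sim\tCDS\t{start}\t{end}\t.\t+\t0\tID=cds{k}"
            )
        density = 100.0 * mask.sum() / spec.length_bp

    insert_map = None
    if spec.insert_plan is not None:
        insert_map = InsertMap(
            gene_id="rrn23S",
            inserts=[Insert(start=s, length=ln) for s, ln in spec.insert_plan],
        )
    return SimulatedAnnotatedGenome(
        record=record,
        gff3="\n".join(lines) + "\n",
        insert_map=insert_map,
        coding_density_truth=density,
    )


def write_fasta(record: GenomeRecord, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in record.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
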