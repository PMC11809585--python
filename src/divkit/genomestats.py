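"""Per-assembly summary statistics for (metagenome-assembled) genomes.

Covers the usual genome-table columns — size, contig count, GC, coding
density, protein and rRNA/tRNA counts — plus two small computations specific
to working with incomplete and insert-bearing genomes:

* the completeness-scaled genome size, ``size / completeness * 100``, the
  expected length of the complete genome given a completeness estimate;
* coordinate remapping across insertions in a marker gene (e.g. self-splicing
  introns in a 23S rRNA gene), converting insert-inclusive positions to the
  insert-free coordinate system used by reference numbering;
* the three-way lifestyle categorisation from a symbiont-classifier score.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

__all__ = [
    "GenomeRecord", "GenomeStats", "Insert", "InsertMap", "INSIDE_INSERT",
    "read_fasta", "genome_stats", "estimated_complete_size",
    "classify_lifestyle", "remap_position",
]


@dataclass
class GenomeRecord:
    """An assembly: named contig sequences plus per-contig circularity."""

    genome_id: str
    contigs: list[tuple[str, str]]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        if any(not s for _, s in self.contigs):
            raise ValueError("contig sequences must be non-empty")

    @property
    def size_bp(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class GenomeStats:
    size_bp: int
    n_contigs: int
    gc_percent: float
    coding_density_percent: float | None = None
    n_proteins: int | None = None
    rrna_counts: tuple[int, int, int] | None = None  # (5S, 16S, 23S)
    trna_count: int | None = None
    est_complete_size_bp: float | None = None


def read_fasta(path: str, genome_id: str | None = None) -> GenomeRecord:
    """Load a (multi-)FASTA assembly; ``circular`` flags default to False."""
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not contigs:
        raise ValueError(f"empty FASTA: {path}")
    return GenomeRecord(genome_id or path, contigs)


def gc_percent(seq: str) -> float:
    """GC over unambiguous bases only: 100·(G+C)/(A+C+G+T)."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return 0.0
    return 100.0 * gc / (gc + at)


def _merged_coverage(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, overlaps merged."""
    covered = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered


def estimated_complete_size(size_bp: int, completeness_percent: float) -> float:
    """Expected complete-genome length: size / completeness × 100."""
    if not 0 < completeness_percent <= 100:
        raise ValueError("completeness must be in (0, 100]")
    return size_bp / completeness_percent * 100.0


def _load_features(annotations):
    if annotations is None:
        return None
    if isinstance(annotations, gffutils.FeatureDB):
        return annotations
    # path or GFF3 text
    text = annotations
    if "\n" not in text and not text.lstrip().startswith("#"):
        with open(text) as fh:
            text = fh.read()
    return gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )


def genome_stats(
    genome: GenomeRecord,
    annotations=None,
    completeness: float | None = None,
) -> GenomeStats:
    """Summary statistics for one assembly.

    ``annotations`` may be a GFF3 path, GFF3 text, or a gffutils FeatureDB;
    CDS features drive coding density (overlaps merged) and the protein
    count, rRNA features are split 5S/16S/23S by their product qualifier,
    and tRNA features are counted.  ``completeness`` (percent, in (0,100])
    switches on the completeness-scaled size estimate.
    """
    lengths = {name: len(seq) for name, seq in genome.contigs}
    all_seq = "".join(seq for _, seq in genome.contigs)
    stats = GenomeStats(
        size_bp=genome.size_bp,
        n_contigs=len(genome.contigs),
        gc_percent=gc_percent(all_seq),
    )
    db = _load_features(annotations)
    if db is not None:
        cds = list(db.features_of_type("CDS"))
        for f in cds:
            if f.seqid in lengths and f.end > lengths[f.seqid]:
                raise ValueError(
                    f"CDS feature {f.id or f.attributes.get('ID', ['?'])[0]!r} "
                    f"extends past end of contig {f.seqid!r}"
                )
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for f in cds:
            per_contig.setdefault(f.seqid, []).append((f.start, f.end))
        covered = sum(_merged_coverage(iv) for iv in per_contig.values())
        stats.coding_density_percent = 100.0 * covered / genome.size_bp
        stats.n_proteins = len(cds)
        rrnas = list(db.features_of_type("rRNA"))
        counts = [0, 0, 0]
        for f in rrnas:
            product = " ".join(f.attributes.get("product", []))
            for i, tag in enumerate(("5S", "16S", "23S")):
                if tag in product:
                    counts[i] += 1
                    break
        stats.rrna_counts = tuple(counts)
        stats.trna_count = sum(1 for _ in db.features_of_type("tRNA"))
    if completeness is not None:
        stats.est_complete_size_bp = estimated_complete_size(genome.size_bp, completeness)
    return stats


# ---------------------------------------------------------------------------
# lifestyle categorisation
# ---------------------------------------------------------------------------

FREE_LIVING = "free-living"
HOST_ASSOCIATED = "symbiont/host-associated"
INTRACELLULAR = "symbiont/intracellular"


def classify_lifestyle(score: float) -> str:
    """Three-way lifestyle category from a symbiont-classifier score.

    score ≤ 0.42 → free-living; 0.42 < score < 1.21 → symbiont/host-associated;
    score ≥ 1.21 → symbiont/intracellular.  Boundaries are exact.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    if score <= 0.42:
        return FREE_LIVING
    if score < 1.21:
        return HOST_ASSOCIATED
    return INTRACELLULAR


# ---------------------------------------------------------------------------
# insert-aware coordinate remapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Insert:
    """One insertion: 1-based start in insert-inclusive coordinates, length."""

    start: int
    length: int

    def __post_init__(self):
        if self.start < 1 or self.length < 1:
            raise ValueError("insert start and length must be positive")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class InsertMap:
    """Ordered, non-overlapping insertions within one gene."""

    gene_id: str
    inserts: list[Insert]

    def __post_init__(self):
        self.inserts = sorted(self.inserts, key=lambda i: i.start)
        for a, b in zip(self.inserts, self.inserts[1:]):
            if b.start <= a.end:
                raise ValueError(f"inserts overlap: {a} and {b}")


class _InsideInsert:
    """Sentinel returned when a position falls within an insert."""

    def __repr__(self):
        return "INSIDE_INSERT"

    def __bool__(self):
        return False


INSIDE_INSERT = _InsideInsert()


def remap_position(pos: int, inserts: InsertMap, gene_length: int | None = None):
    """Convert an insert-inclusive position to insert-free coordinates.

    Subtracts the total length of inserts lying entirely upstream of ``pos``.
    A position inside an insert has no insert-free equivalent and returns the
    ``INSIDE_INSERT`` sentinel instead of a number.
    """
    if pos < 1:
        raise ValueError("positions are 1-based")
    if gene_length is not None and pos > gene_length:
        raise ValueError(f"position {pos} exceeds gene length {gene_length}")
    upstream = 0
    for ins in inserts.inserts:
        if ins.end < pos:
            upstream += ins.length
        elif ins.start <= pos <= ins.end:
            return INSIDE_INSERT
    return pos - upstream
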