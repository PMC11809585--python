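"""Fragment-based average nucleotide identity (ANI) and species clustering.

The estimator follows the fragment paradigm of whole-genome ANI tools: the
query is cut into consecutive, non-overlapping 3 kb fragments; each fragment
is placed on the reference (both strands) by exact 16-mer seeding with
best-diagonal voting and then aligned, in infix mode, against the candidate
window; fragments reaching 80% alignment identity count as mapped, and the
ANI is the mean identity over mapped fragments.  The aligned fraction —
mapped fragments × fragment length over the smaller genome — gates a
reliability flag (default floor 0.2), mirroring the ``--minFraction``
semantics of the cited-tool defaults.

Species delineation clusters genomes as connected components of the graph
with an edge whenever the better of the two directional ANIs exceeds the
threshold (conventionally >95%) and that direction is reliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np

from .genomestats import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = ["ANIResult", "SpeciesClustering", "compute_ani", "cluster_species"]

_K = 16
_BAND = 40
_MIN_SEED_VOTES = 3

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ANIResult:
    query_id: str
    reference_id: str
    ani_percent: float | None
    fragments_total: int
    fragments_mapped: int
    aligned_fraction: float
    reliable: bool


@dataclass
class SpeciesClustering:
    clusters: list[set[str]]
    threshold_percent: float


def _kmer_codes(seq: str, k: int = _K) -> tuple[np.ndarray, np.ndarray]:
    """(codes, start_positions) of all unambiguous k-mers in ``seq``."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(arr) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win.astype(np.int64) @ powers
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


class _ReferenceIndex:
    """Sorted k-mer table over the concatenated reference contigs."""

    def __init__(self, genome: GenomeRecord, k: int = _K):
        # join contigs with k Ns so no k-mer spans a contig boundary
        self.seq = ("N" * k).join(seq for _, seq in genome.contigs)
        codes, pos = _kmer_codes(self.seq, k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]

    def best_diagonal(self, frag_codes: np.ndarray, frag_pos: np.ndarray) -> tuple[int, int]:
        """(diagonal, votes) of the best seed diagonal; votes 0 if none."""
        if len(frag_codes) == 0 or len(self.sorted_codes) == 0:
            return 0, 0
        left = np.searchsorted(self.sorted_codes, frag_codes, side="left")
        right = np.searchsorted(self.sorted_codes, frag_codes, side="right")
        unique = (right - left) == 1  # skip repetitive seeds
        if not unique.any():
            return 0, 0
        diag = self.sorted_pos[left[unique]] - frag_pos[unique]
        lo = diag.min()
        votes = np.bincount(diag - lo)
        best = int(votes.argmax())
        return int(lo + best), int(votes[best])


def _fragment_identity(fragment: str, index: _ReferenceIndex, diag: int, band: int = _BAND) -> float:
    start = max(diag - band, 0)
    end = min(diag + len(fragment) + band, len(index.seq))
    window = index.seq[start:end]
    if not window:
        return 0.0
    res = edlib.align(fragment, window, mode="HW", task="path")
    cigar = res.get("cigar") or ""
    columns = sum(int(n) for n in _split_cigar_lengths(cigar))
    if columns == 0:
        return 0.0
    return (columns - res["editDistance"]) / columns


def _split_cigar_lengths(cigar: str) -> list[str]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append(num)
            num = ""
    return out


def _fragments(genome: GenomeRecord, frag_len: int) -> list[str]:
    frags: list[str] = []
    for _, seq in genome.contigs:
        if len(seq) < frag_len:
            frags.append(seq)
            continue
        frags.extend(
            seq[i: i + frag_len]
            for i in range(0, len(seq) - frag_len + 1, frag_len)
        )
    return frags


def compute_ani(
    query: GenomeRecord,
    reference: GenomeRecord,
    frag_len: int = 3000,
    min_fraction: float = 0.2,
    identity_floor: float = 0.8,
) -> ANIResult:
    """Directional ANI of ``query`` against ``reference``.

    A genome shorter than ``frag_len`` contributes a single full-length
    fragment (warned).  With no mapped fragments the ANI is undefined
    (``None``) and the result is flagged unreliable.
    """
    if frag_len < 100:
        raise ValueError("frag_len must be >= 100")
    if query.size_bp == 0 or reference.size_bp == 0:
        raise ValueError("genomes must be non-empty")
    if query.size_bp < frag_len:
        logger.warning(
            "query %s shorter than fragment length; using one full-length fragment",
            query.genome_id,
        )

    index = _ReferenceIndex(reference)
    identities = []
    frags = _fragments(query, frag_len)
    for frag in frags:
        best_identity = 0.0
        for oriented in (frag, _revcomp(frag)):
            codes, pos = _kmer_codes(oriented)
            diag, votes = index.best_diagonal(codes, pos)
            if votes < _MIN_SEED_VOTES:
                continue
            ident = _fragment_identity(oriented, index, diag)
            best_identity = max(best_identity, ident)
        if best_identity >= identity_floor:
            identities.append(best_identity)

    mapped = len(identities)
    aligned_fraction = min(
        mapped * frag_len / min(query.size_bp, reference.size_bp), 1.0
    )
    return ANIResult(
        query_id=query.genome_id,
        reference_id=reference.genome_id,
        ani_percent=100.0 * float(np.mean(identities)) if mapped else None,
        fragments_total=len(frags),
        fragments_mapped=mapped,
        aligned_fraction=aligned_fraction,
        reliable=mapped > 0 and aligned_fraction >= min_fraction,
    )


def cluster_species(
    results: list[ANIResult],
    threshold_percent: float = 95.0,
    genomes: list[str] | None = None,
) -> SpeciesClustering:
    """Connected-component species clusters from all-pairs ANI results.

    Two genomes join when the better of the two directional ANIs is strictly
    above ``threshold_percent`` and that direction is reliable.  Genomes with
    no qualifying edge form singleton clusters.  ``genomes``, if given, fixes
    the universe; result ids outside it raise.
    """
    ids = set(genomes) if genomes is not None else set()
    for r in results:
        if genomes is not None and not {r.query_id, r.reference_id} <= ids:
            raise ValueError(
                f"result {r.query_id} vs {r.reference_id} names unknown genome ids"
            )
        ids.update((r.query_id, r.reference_id))

    best: dict[frozenset, tuple[float, bool]] = {}
    for r in results:
        if r.query_id == r.reference_id or r.ani_percent is None:
            continue
        key = frozenset((r.query_id, r.reference_id))
        prev = best.get(key)
        if prev is None or r.ani_percent > prev[0]:
            best[key] = (r.ani_percent, r.reliable)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for key, (ani, reliable) in best.items():
        if ani > threshold_percent and reliable:
            graph.add_edge(*key)
    clusters = sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c)[0],
    )
    return SpeciesClustering(clusters=clusters, threshold_percent=threshold_percent)
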