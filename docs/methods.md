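# Methods

## Trees and the GTDB label dialect

Trees are rooted phylogenies with non-negative branch lengths in
substitutions/site. Internal nodes may carry compound labels of the form
`'support:taxon1; taxon2'` as written by GTDB release trees; the first
colon inside the (quoted) label separates the support from the taxon list.
Parsing is delegated to dendropy; the compound-label splitting and the
writer are our own. The writer formats branch lengths with shortest
round-trip float representation, so parse–write cycles are lossless on
topology, lengths, supports and labels. A missing branch length is read as
0 with a warning; negative lengths and duplicate leaf names are errors.

## Taxonomic decoration

Each taxon at a requested rank is placed on the single node maximising
F = 2PR/(P+R), where precision P and recall R compare the node's
descendant-leaf set with the taxon's member-leaf set. Ties break by
(1) fewer descendant leaves, (2) smaller depth from the root, (3)
lexicographically smallest descendant leaf name — a deterministic rule,
since published decorations do not specify one. A taxon with exactly one
member leaf is placed on that leaf and flagged singleton. We deliberately
place one node per taxon; polyphyletic taxa are not split, but their
achieved F < 1 is reported so users can detect them. Exact concordance with
other decoration tools' tie handling is therefore not guaranteed.

## RED

red(n) = red(p) + (d/u)·(1 − red(p)), with u = d + mean node-to-leaf path
length. The root is 0 and every leaf exactly 1 (for a leaf u = d). Design
choices for edge cases: a subtree whose branch lengths are all zero
(u = 0) inherits the parent's RED, the limit of the formula; computed
values are clamped to [red(parent), 1] so the table invariants survive
rounding; multifurcations are handled natively; any stem on the root is
ignored. RED is invariant to rescaling all branch lengths by a positive
constant, and on an ultrametric tree equals depth/total-depth — both are
verified properties. Median-of-rootings RED averaging is out of scope, so
numeric concordance with tools that average over rootings is approximate.

## PD profiles

PD(taxon) = subtree branch sum + stem at the placed node; leaf stem alone
for singletons; for a taxon placed at the root the stem contribution is 0
(logged). Fractions divide by the total over all taxa at the rank —
including singletons — and sum to 1 within 1e-9 (math.fsum). Ranking is
dense on descending fraction with lexicographic tie-breaking. The adjusted
profile recomputes RED, rescales the tree, and re-measures subtree sums and
stems in RED units, with placements computed once on the original tree and
carried over. An optional consolidation flag merges taxa whose names differ
only by a polyphyly suffix (`_A`, `_B`, ...), summing their raw PD; merging
happens after per-taxon PD computation and before normalisation and
ranking, so the denominator is unchanged and only the ranking granularity
differs.

## Fragment ANI

The query is cut into consecutive non-overlapping 3000 bp fragments
(default; trailing partial fragments are dropped, except that a genome
shorter than one fragment contributes a single full-length fragment).
Candidate placement uses exact 16-mer seeds: reference k-mers are indexed
in a sorted array; fragment seeds with a unique reference hit vote for a
diagonal, and the best diagonal (≥ 3 votes, both strands tried) defines a
reference window padded by 40 bp. The fragment is aligned to the window
with edlib in infix mode — the fragment is aligned globally, the window
flanks are free — and identity = (alignment columns − edit distance) /
columns. Fragments at ≥ 80% identity count as mapped; ANI is the mean
identity over mapped fragments; the aligned fraction is
mapped × fragment-length / min(genome sizes), and results with aligned
fraction below 0.2 (default) are flagged unreliable. Dropping repetitive
(non-unique) seeds means a genome that is one short tandem repeat cannot be
seeded; real assemblies and the simulated genomes are far from this regime.
With substitution-only divergence the estimator recovers 100·(1 − d) within
0.5 points for d ≤ 0.05 on ≥ 300 kb pairs, is exactly 100 on self-comparison,
and is invariant to reverse-complementing the reference (to ~0.05 points;
edlib may break alignment ties differently per strand).

Species clustering takes all-pairs results and connects two genomes when
the better of the two directional ANIs is strictly above the threshold
(default 95, i.e. "ANI > 95%") *and* that direction is reliable; species
are the connected components, with isolated genomes as singleton clusters.

## Genome statistics

GC uses only unambiguous bases in the denominator (standard convention).
Coding density merges overlapping CDS intervals before summing coverage,
preventing densities above 100%. rRNA features are split 5S/16S/23S by
their `product` qualifier; nothing is predicted de novo. The
completeness-scaled genome size is size/completeness × 100, defined for
completeness in (0, 100]; at 100% it equals the assembly size exactly.
Lifestyle categorisation applies the published score thresholds with exact
boundary semantics: score ≤ 0.42 free-living, 0.42 < score < 1.21
symbiont/host-associated, score ≥ 1.21 symbiont/intracellular.

Coordinate remapping treats all positions as 1-based inclusive. A position
in insert-inclusive gene coordinates maps to the insert-free system by
subtracting the lengths of inserts entirely upstream; positions inside an
insert have no insert-free equivalent and return a distinct sentinel
(`INSIDE_INSERT`) rather than a number. The map is strictly increasing
outside inserts and never increases a coordinate. Insert discovery (e.g. by
alignment to a 23S model) is out of scope; inserts are user-supplied.

## Synthetic data

Trees: each non-singleton phylum is an independently simulated timed
pure-birth (Yule) subtree — lineages split at exponential waiting times,
tips extended to a common end time — joined under a shared root, so every
planted taxon is monophyletic by construction. In ultrametric mode each
phylum crown is rescaled to a uniform(0.3, 0.8) depth with the stem making
every leaf sit at depth exactly 1; otherwise every branch receives
independent lognormal rate jitter (σ = 0.6), emulating a phylogram. Ranks
below phylum follow the subtree's own nesting (children of the crown anchor
the classes, and so on to genus; lineages are padded where a branch bottoms
out early), and species are one per leaf. Rate inflation multiplies every
branch strictly inside a chosen phylum's crown subtree, reproducing the
standard-vs-adjusted PD divergence expected for rapidly evolving clades.
The truth table records each planted taxon's anchor and exact raw PD via
the generator's own bottom-up bookkeeping.

Genomes: i.i.d. bases with per-base GC probability equal to the target;
divergence d plants round(d·L) substitutions at distinct uniform sites,
each to a different base, so the observed mismatch fraction equals the
bookkept count exactly and ANI recovery has a closed-form target of
100·(1 − d). Defaults (500 kb pairs, GC 0.354 where a low-GC organism is
being emulated, divergences of 1–6%) match the scale at which species-level
ANI comparisons operate. What the generator does *not* emulate: indels,
rate heterogeneity across sites, repeats, horizontal transfer, and
assembly artefacts — so passing tests show estimator correctness under the
stated substitution model, not robustness to real-genome complications.
Every generator is a pure function of its spec; identical specs give
byte-identical output from a single `numpy.random.default_rng(seed)`.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: trees of
20–500 leaves (50 trees for the RED closed-form check, 100 (tree, node)
pairs for the PD oracle, 20 seeds for the rate-inflation property) and
genome pairs of 200–500 kb — sizes at which every check completes in
seconds while exercising the same code paths as reference-scale trees.
Tolerances: 1e-9 for the RED/PD bookkeeping identities (pure arithmetic),
0.5 ANI points for divergence recovery (alignment tie-breaking and window
effects), 0.05 points for strand invariance. Reproducing published
reference-scale numbers (e.g. phylum PD fractions on a GTDB release tree)
requires downloading the pinned release tree and accessioned assemblies;
the CLI accepts those files directly, but no network access is assumed
anywhere in the package or its tests.
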