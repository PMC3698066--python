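# Methods

This note records the models, conventions and numerical choices behind
`phagemarker`, and what the synthetic experiments do and do not establish
about real phage data.

## Classification model

The classifier operationalizes visual dotplot inspection of a single marker
gene. For a query *q* and reference *r*, similarity is **word coverage**

    cov(q, r) = |{ i : q[i:i+w] occurs in r }| / (|q| − w + 1)

with word length *w* = 10 for nucleotide and 3 for amino-acid sequences —
standard dotplot word sizes; *w* is configurable because coverage scales
steeply with it (per-word match probability ≈ identityʷ). The call is the
subcluster of the arg-max reference. Exact ties are broken by
global-alignment percent identity, then lexicographically by reference id,
so calls are deterministic.

**Unassigned threshold 0.25.** True singletons share on the order of 10%
marker-gene coverage with any assigned cluster, while divergent genuine
members still reach ~40–50%. A coverage floor of 0.25 separates the two
regimes and is exposed as a flag. Word coverage of ~0.37 corresponds to
~90% sequence identity at w = 10, so the default accepts members down to
roughly 85–90% identity and rejects anything without a sustained homologous
backbone.

**Recovery statistics.** Accuracy is correct/n at cluster and subcluster
level (unassigned = incorrect), with the normal-approximation (Wald)
interval p ± z₀.₉₇₅√(p(1−p)/n) on the **unrounded** proportion. Note that
for 244/247 the unrounded convention yields a half-width of 1.37 at two
decimals, whereas computing on p pre-rounded to 0.988 yields 1.36; we use
the unrounded value. At p ∈ {0, 1} the Wald width is exactly 0 — a known
degeneracy of the interval, reported as-is.

## Alignment

Global alignment uses free end gaps, match +5.0, mismatch −4.0, and affine
gaps where a gap of length k costs `open + (k−1)·extend` = 12 + 3(k−1)
(Biopython's convention; the scores are the classic 65%-similarity recipe
used for marker-gene comparisons). Percent identity is counted over aligned
columns where at least one row has a residue; under free end gaps the
leading/trailing single-sequence overhangs are excluded from the
denominator (switchable), since unaligned overhangs say nothing about
homologous divergence. Tie-breaking among co-optimal alignments follows the
backing aligner's first reported path; scores are unaffected.

The multiple aligner is a compact progressive scheme: pairwise identity
distances → NJ guide tree → profile–profile merges with the same scoring
parameters (Gotoh three-state DP on column profiles; ties resolve
diagonal > up > left). It is an approximation in the ClustalW mould, not a
clone of any particular tool; identity statistics on its output are
therefore tolerance-based, except for fully conserved inputs where
100.00%/100.00% is exact.

## Primer design

Conserved windows are gap-free blocks of 16–22 alignment columns whose
column-wise **minimal IUPAC consensus** (smallest code covering the
observed bases) has at most 3 degenerate columns; any gap disqualifies a
window because synthesised primers are fixed-length. The degeneracy budget
absorbs silent third-position substitutions without collapsing specificity.
Primer pairs are (upstream consensus, reverse complement of downstream
consensus) with the predicted product length — inclusive of both primer
footprints, 1-based — required to fall in a target range (default
150–900 bp, bracketing practical gel-readable products) on every alignment
row. Pairs are ranked by total degeneracy (product of per-base set sizes,
capped at 64) then product length. Highly conserved alignments yield
thousands of overlapping windows, so pairing considers the best
`max_candidates` (150) windows per orientation by default; `None` restores
the exhaustive quadratic.

In-silico PCR matches the forward primer IUPAC-wise on the plus strand and
the reverse primer as its reverse complement downstream, screens both
template orientations (so results are strand-symmetric), reports all
pairings up to a 5 kb product cap, and treats template `N` as matching
nothing by default (conservative; a flag relaxes it). Melting temperature,
hairpin and dimer checks are deliberately out of scope — specificity here
is a sequence question, not a thermodynamic one.

## Alignment-free phylogenetics

A feature frequency profile (FFP) is the count map of all length-L words of
a sequence (default L = 20, suited to whole phage genomes); windows
containing non-ACGT characters are skipped. Profile divergence is
**Jensen–Shannon** (the FFP literature's standard measure; symmetric,
bounded by ln 2, zero iff the normalized profiles coincide), computed over
shared features plus the disjoint mass so cost scales with the typically
small intersection. Trees are neighbor-joining (dendropy); negative NJ
branch lengths are clamped to zero with a warning. Bootstrap resampling
draws features (columns of the taxa × feature count table) with replacement
for FFP data, or alignment columns for MSA-derived distances; splits
occurring in > 50% of replicates form the majority-rule consensus, with
percent occurrence as support.

**Matching Splits** is the minimum-cost perfect matching between two trees'
non-trivial bipartition sets; the cost of a split pair is the smaller
symmetric-difference size over the two side pairings, computed with the
Hungarian algorithm. Unequal set sizes are padded with dummy splits; a real
split matched to a dummy costs the size of its smaller side (this fixes the
padding convention the metric needs). The percent-of-star normalization
divides by the distance to a completely unresolved star tree on the same
leaves, so 100% means "as different as no resolution at all".

**gsi.** For a group of n leaves, gs = (n−1) / Σᵤ(cᵤ−1) over the uniting
nodes u (internal nodes on the paths from group leaves to their MRCA, with
cᵤ children each); gsi rescales gs between its minimum on that tree (group
dispersed across every internal node) and 1:
gsi = (gs − gs_min)/(1 − gs_min). A group whose bipartition exists as a
tree edge scores exactly 1. Unrooted trees use their seed node as the root
for path-walking; monophyly itself is tested as split existence and is
therefore rooting-independent.

## Synthetic panels

`generate_panel` emulates a curated collection: one random ancestor per
cluster (independent ancestors by default, because real clusters share
little nucleotide similarity; an optional shared-root mode supports
experiments needing a connected deep phylogeny), a subcluster ancestor
diverged at the within-cluster rate (default 0.20), and members diverged at
the within-subcluster rate (default 0.05 → ~90% pairwise member identity,
a tight subcluster). Genomes default to 20 kb with a 3 kb marker gene at a
fixed locus — the marker-to-genome ratio of real siphovirus TMP genes.
Substitutions are uniform across bases (Jukes–Cantor-like; adequate for
identity-level behaviour, not a biological substitution model). Indels
(geometric lengths, off by default) are confined outside the marker locus
so truth intervals remain exact. Mosaic swaps replace a random 5–15%
segment with the homologous-position segment of another cluster's genome,
never touching the marker by default — mirroring the hypothesized
evolutionary stability of tail-structure genes — and are recorded in the
truth table.

What the generator does **not** model: gene content and synteny variation,
compositional bias, codon structure, recombination hotspots, and
heterogeneous conservation along the gene. Passing tests on synthetic
panels therefore demonstrate the machinery's correctness and the method's
behaviour under controlled divergence, not its accuracy on any real
collection.

## The genome-versus-marker tree experiment

The alignment-free comparison (acceptance test and script) uses a panel
with within-subcluster divergence 0.15 (~73% pairwise member identity,
matching the looser subclusters of real collections) and within-cluster
divergence 0.25. At these distances shared 20-mers become scarce on a 3 kb
gene (a few per related pair) while a 20 kb genome retains dozens, so
genome trees recover subcluster clades and marker-gene trees recover fewer
— the length effect the single-gene caveat is about. At the generator's
default tightness (0.05) the synthetic marker still shares hundreds of
20-mers within subclusters and alignment-free trees remain fully resolved
at any word length; the uniform-composition model simply has no mechanism
to degrade them there. That boundary is worth keeping in mind when mapping
these results onto real data, where heterogeneous conservation makes the
short-gene failure more severe than the simulation suggests.

## Problem sizes and determinism

Default experiment sizes: 40-member panels (5 × 2 × 4) for leave-one-out
classification, 18 templates / 6 primer sets for the cross-reactivity
screen, 30 genomes (5 × 2 × 3) for the tree comparison; bootstrap examples
use tens of replicates in tests (the API default is 10 000). All
randomness flows from explicit seeds (numpy Generators); identical
config + seed reproduces byte-identical FASTA output.

## Known limitations

* The Wald interval misbehaves near p ∈ {0, 1} (zero width); no
  continuity-corrected or score interval is provided because the reported
  statistics follow the proportion-CI convention above.
* The progressive aligner is O(L²) per merge and meant for marker-gene
  scale (a few kb, tens of sequences), not genome alignments.
* Whole-genome dotplots work but are unoptimized (word-table, no suffix
  arrays).
* Maximum-likelihood and Bayesian tree inference are out of scope; trees
  from external tools can be read as newick and evaluated with the same
  Matching Splits / gsi machinery.
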