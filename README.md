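# phagemarker

Single marker-gene classification for bacteriophages.

Curated phage collections (most prominently the mycobacteriophages) are
organised into **clusters** and **subclusters** by whole-genome comparison.
Sequencing a whole genome is the gold standard but is slow and expensive at
the isolation stage. `phagemarker` implements the single-gene shortcut: one
long, ubiquitous, semi-conserved structural gene — canonically the
tape-measure protein (TMP) gene, ~3 kb in siphoviruses — carries enough
signal to predict the cluster and subcluster of a phage, to design
subcluster-specific degenerate PCR primers, and to study where the
single-gene approximation breaks down.

The toolkit is aimed at phage genomicists and teaching labs (e.g.
phage-hunting courses) who want cluster predictions from a single
PCR-amplifiable gene, plus the statistics to quantify how well those
predictions track whole-genome taxonomy.

## What it computes

* **Dotplot classification** — a query gene is compared to every member of a
  labelled reference panel by exact word matches (word length 10 nt / 3 aa).
  The similarity score is *word coverage*: the fraction of the query's words
  found anywhere in a reference. The call is the subcluster of the
  best-covered reference; queries under a coverage threshold (default 0.25)
  are left **unassigned**, the behaviour of true singletons. Recovery
  accuracy is reported with the Wald interval
  p ± z₀.₉₇₅ √(p(1−p)/n).
* **Alignment statistics** — global alignment with free end gaps, match 5 /
  mismatch −4, affine gaps (open 12, extend 3; a gap of length k costs
  12 + 3(k−1)); progressive MSA over an NJ guide tree; per-alignment
  "% identical sites" and mean pairwise identity.
* **Degenerate primer design** — gap-free conserved windows of 16–22
  alignment columns whose minimal IUPAC consensus has ≤ 3 degenerate
  positions; window pairs become primer pairs constrained to a product
  range; in-silico PCR (IUPAC-aware, both strands) validates products and
  screens for cross-reactivity against other subclusters.
* **Alignment-free phylogenetics** — feature frequency profiles (20-mer
  counts), Jensen–Shannon divergence, neighbor-joining trees, bootstrap
  majority-rule consensus, the **Matching Splits** tree distance with
  percent-of-star normalization, and the **genealogical sorting index**
  (gsi ∈ [0,1], 1 ⇔ monophyly) per labelled group.
* **Synthetic panels** — cluster-structured genomes with an embedded marker
  gene, tunable divergences, indels and cross-cluster mosaic segment swaps,
  plus a truth table, so the whole pipeline is testable without downloads.

## Worked example

```bash
# generate a labelled synthetic panel (10 subclusters x 4 members)
phagemarker synth --clusters 5 --sub 2 --members 4 --seed 42 --out panel/

# classify every marker gene against the rest of the panel (leave-one-out)
phagemarker classify --panel panel/tmp.fasta --labels panel/truth.tsv \
    --query panel/tmp.fasta --loo --out calls.tsv
phagemarker evaluate --calls calls.tsv --truth panel/truth.tsv
```

which prints

```
n	40
cluster_correct	40
subcluster_correct	40
cluster_accuracy_pct	100.0
subcluster_accuracy_pct	100.0
ci_halfwidth_pct	0.0
```

i.e. every one of the 40 panel members is returned to its own subcluster by
word coverage against the remaining 39, with a degenerate Wald half-width of
0 at p = 1. The same panel drives primer design:

```bash
phagemarker primers design --msa subA1.afa --group A1 --range 150:900 --out pairs.tsv
phagemarker primers pcr --template panel/tmp.fasta --pairs pairs.tsv
```

and the tree side:

```bash
phagemarker ffp-tree --fasta panel/genomes.fasta -L 20 --out genomes.nwk
phagemarker treecmp --t1 genomes.nwk --t2 marker.nwk
phagemarker gsi --tree genomes.nwk --labels panel/truth.tsv
```

The library mirrors the CLI one-to-one (`phagemarker.classify_gene`,
`design_primer_pairs`, `insilico_pcr`, `ffp_profile`, `nj_tree`,
`matching_splits`, `gsi`, `generate_panel`, ...); see `docs/methods.md` for
the model details and parameter rationale.

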