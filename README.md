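# mybkit

A gene-family annotation toolkit for plant **R2R3-MYB transcription
factors**, built around the banana (*Musa acuminata*, DH-Pahang)
family survey design. It is aimed at researchers who need to turn a set
of candidate proteins, gene models and RNA-Seq quantifications into a
curated, classified and expression-annotated MYB family catalog —
without re-running the upstream genome-scale searches.

## What it computes

MYB proteins are defined by tandem, imperfect repeats (R) of ~50–53
amino acids, each contributing three regularly spaced tryptophan (or
hydrophobic) core residues to a helix–turn–helix fold. The toolkit
covers the five analysis stages of a family survey:

1. **Repeat scanning** (`mybkit.domain_scan`) — Smith–Waterman local
   alignment of each protein against a repeat profile (per-position
   BLOSUM62 scores over a consensus, linear gaps), with greedy
   mask-and-repeat search for tandem copies. Architectures are typed by
   repeat count: 0 → none, 1 → 1R, 2 → R2R3, 3 → 3R (R1R2R3), ≥4 → 4R;
   only multi-repeat proteins enter the family catalog.
2. **bHLH-interaction motif** (`mybkit.motif_scan`) — exhaustive scan
   for the consensus `[D/E]Lx2[R/K]x3Lx6Lx3R` that marks R2R3-MYBs able
   to join MYB–bHLH–WD40 (MBW) complexes.
3. **Phylogenetic clade assignment** (`mybkit.phylo`) — p-distances
   over pairwise/center-star alignments, Saitou–Nei neighbor-joining
   with deterministic tie-breaking, column-resampling bootstrap with a
   majority-rule consensus, and assignment of each query to the
   smallest well-supported clade containing labelled references.
   Cohesive query-only clades with no unambiguous labelled context are
   flagged `lineage-specific:k`.
4. **Structure statistics** (`mybkit.catalog`) — GFF3 parsing
   (gene/mRNA/exon/CDS), exon-count histograms, chromosome
   distributions over the `Ma01`–`Ma11` pseudochromosomes plus the
   unplaced `Ma00` bin, and assembly of the per-gene catalog.
5. **Expression breadth** (`mybkit.expression`) — FPKM
   (`counts × 10⁹ / (length × total)`), breadth classes
   (all-samples / none / some), organ-exclusive calls over six organ
   groups, and paralog profile comparison (Pearson on log₂(FPKM+1),
   Jaccard of expressed-organ sets).

A synthetic-data generator (`mybkit.synthetic`) plants repeats, motifs,
exon structures, clade memberships and expression patterns with a truth
manifest, so every stage is testable offline. Two packaged tables —
the 294-gene catalog and the 293 × 17 FPKM matrix of the banana survey
— provide the real-data surface.

## Worked example

```sh
python analysis/01_simulate_family.py
python analysis/02_scan_repeats.py
python analysis/05_catalog_statistics.py
python analysis/06_expression_breadth.py
```

prints

```
generated 45 genes (35 retained multi-repeat), 18 labelled references -> .../results/bundle
recovered 82/82 planted repeat intervals (100.0%) across 45 proteins -> results/scan.tsv
294 genes: 285 R2R3 + 6 3R + 2 4R + 1 CDC5; 291 placed, 3 unplaced; 3-exon mode 155 (54.4%); 30 bHLH-motif genes; family share 0.81% of protein-coding, 9.0% of TF genes -> results/catalog_summary.json
293 genes: 13 silent, 280 expressed in >=1 sample, 43 in all samples; organ totals root 221, pulp 209, leaf 203, peel 196; paralog organ overlap 1.00 vs 0.17 -> results/expression_summary.json
```

Reading the numbers: the simulated family is recovered perfectly by the
scanner (every planted repeat interval found, none spurious). On the
packaged catalog, the dominant gene structure is the conserved
three-exon/two-intron arrangement (155 of 285 R2R3 genes, 54.4%), 30
proteins carry the bHLH-interaction motif, and the family makes up
0.81% of all protein-coding genes. On the packaged expression table, 13
genes are silent across all 17 samples, roots express the most MYB
genes (221), and the two paralog pairs contrast sharply: one pair
shares every expressed organ (Jaccard 1.0), the other barely overlaps
(0.17) because the second copy is nearly silent.

The same stages are available as subcommands of the `mybkit` CLI
(`scan`, `motif`, `tree`, `catalog`, `express`, `simulate`, `run`).

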