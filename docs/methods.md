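# Methods

This note documents the models, parameter choices and numerical
conventions behind mybkit, and what the synthetic benchmark does and
does not demonstrate about real data.

## Repeat model and scanning

A MYB repeat is modelled as a `RepeatProfile`: a consensus sequence
(default: a package-authored 52-residue R2R3-type consensus with
tryptophans at positions 6, 26 and 46, i.e. regular ~20-residue
spacing) plus per-position substitution scores. By default position
*i* scores amino acid *a* as `BLOSUM62[consensus[i], a]`, reflecting
that family surveys of this kind are seeded by BLAST-family searches.
The consensus is a default only — every scanning entry point accepts a
replacement profile (e.g. a lab's own curated consensus), and nothing
downstream depends on its exact content.

`score_window` is plain Smith–Waterman local alignment against the
profile (linear gap penalty, default −6; all scores are integer-valued,
so floating-point equality in the traceback is exact). `detect_repeats`
finds tandem copies greedily: best local hit, mask, repeat. Greedy
masking matches the geometry of tandem repeats (hits cannot overlap)
and is deterministic — score ties are broken toward the smaller start
coordinate, and traceback ties resolve diagonal > up > left.

Parameters that matter:

- `min_score` (score floor): default 0.5 × the profile self-score.
  This is permissive enough for diverged repeats while keeping the
  false-hit rate on random sequence effectively zero (a random
  ~40-residue stretch scores far below half of the ~291 self-score of
  the default profile).
- `min_len` (default 45 residues): a hit spanning less than this is
  masked but not reported, implementing the "intact repeat"
  requirement.
- Tryptophan anchors are *reported*, not required: each hit carries the
  count of anchor positions (of 3) occupied by W/F/Y/L/I/M/V, because
  the third core position is frequently a non-W hydrophobic residue.
  Downstream filtering can use the count; the scanner does not.

Architecture typing is a pure function of repeat count
(0/1/2/3/≥4 → none/1R/R2R3/3R/4R). CDC5-like proteins are
two-repeat MYB-related proteins identified by orthology, not by repeat
geometry; they enter the catalog via explicit annotation (`cdc5_ids`),
never by sequence classification.

## Motif scan

The bHLH-interaction consensus `[D/E]Lx2[R/K]x3Lx6Lx3R` is a pure
positional pattern over 20-residue windows: six constrained positions,
fourteen wildcards. `x` matches any standard residue including X; X
never satisfies a constrained position. All overlapping occurrences
are reported (downstream only uses presence/absence). The scan is
applied to whole proteins; hit positions can be compared with detected
repeat coordinates by the caller, but no repeat-local filtering is
imposed, since requiring the motif to lie inside the R3 repeat is a
biological judgement the toolkit should not hard-code.

## Distances, neighbor-joining, bootstrap

Pairwise distances are p-distances (mismatched / compared columns,
gap-containing columns excluded) over deterministic Needleman–Wunsch
global alignments (default match 1 / mismatch −1 / gap −2). A pair
with no comparable columns is saturated and assigned distance 1. A
Poisson correction `−ln(1 − p)` is available by flag but is not the
default: classification into clades needs a monotone dissimilarity, not
an unbiased substitution-rate estimate.

For bootstrapping, a master alignment is built by center-star
progressive alignment (center = sequence with the highest total
pairwise score; "once a gap, always a gap" merging), or supplied
pre-aligned. Center-star is a deliberate simplification: it is
deterministic, dependency-free and adequate for the short (~50–60
column) domain blocks this toolkit aligns; for full-length or highly
gapped proteins a dedicated aligner should be used upstream and passed
in pre-aligned.

Neighbor-joining follows the Saitou–Nei Q-criterion with two fixed
conventions: ties in Q are broken by the lexicographically smallest
pair of cluster representative ids, and negative branch-length
estimates are clamped to zero (the clamp count is kept on the tree).
The final three clusters join at a trifurcating root via the
three-point formulas, leaving the tree unrooted.

Bootstrap resamples alignment columns with replacement (one RNG stream,
fixed seed recorded in run metadata; default B = 1000, tests and the
synthetic analyses use B = 50–100 at their smaller problem sizes).
Replicate trees are summarised as a >50% majority-rule consensus;
internal edges carry percent support, branch lengths are means over the
replicates containing the edge. Majority splits are mutually
compatible, so the consensus construction (insert splits by decreasing
frequency) cannot fail; an incompatible lower-frequency split is
skipped.

## Clade assignment

The tree is unrooted, so a "clade" is one side of an edge. For each
query, the assignment rule finds all minimal-size clades that contain
the query plus at least one labelled reference and whose edge support
passes the threshold (default 50%); the reference-majority label is
assigned, with two sources of "unresolved": a tie in the majority
within a clade, or disagreeing calls between size-tied minimal clades.

Lineage-specific (reference-free) clades: a maximal well-supported
clade of ≥ 2 query-only leaves is a novel clade — *unless* it is
nested inside some label's own reference clade, defined as the minimal
supported clade spanning that label's references (for a label with a
single reference, the test degrades to: the smallest clade holding the
component plus that reference contains no foreign label). Nested
components are ordinary within-clade expansion and inherit the label
through the normal rule; everything else is reported as
`lineage-specific:k`. The distinction matters because a genuinely
novel clade typically *attaches as a sister* to some labelled clade —
often with weak support — and sisterhood must not be mistaken for
membership, while a burst of query duplicates inside a labelled clade
must not be mistaken for novelty. Nestedness within the references'
own spanning clade separates the two cases without any distance
threshold.

## Gene structure and catalog

GFF3 parsing (via gffutils) produces one gene model per gene; the exon
count comes from the exon features of the longest transcript, with
CDS-based counting behind a flag. The distinction matters when UTR
exons exist; the packaged catalog's counts are "coding exons" as
printed, and the fixture tests pin the exon-feature mode, which
reproduces the printed histogram. Percentages are rounded half-up to
one decimal, matching the printed precision (54.4%, 23.5%, …);
`family_share` takes a `decimals` argument because the two printed
shares use different precisions (0.81% vs 9.0%). Catalog order is
pseudochromosome `Ma01`…`Ma11`, then the unplaced `Ma00` bin, then
start coordinate — the printed table's order, which the serialiser
reproduces byte-identically.

## Expression

FPKM is `counts × 10⁹ / (length_nt × mapped_total)`. "Expressed" means
FPKM strictly above a threshold whose default is 0 — the survey never
states a cutoff, and >0 reproduces the qualitative behaviour of the
printed rows. The 17 samples map onto six organ groups (embryogenic,
seedling, root; leaf = leaf + young/adult/old leaf; pulp = pulp +
S1–S4; peel = peel + S1–S4), configurable via an organ-map TSV.

Two organ-level views exist deliberately:

- `organ_expressed_counts` pools every member sample of an organ
  (a gene is expressed in "leaf" if any leaf-stage sample is on). This
  is the view used for breadth and organ-exclusivity calls.
- `organ_representative_counts` counts only the aggregate column named
  like the organ ("pulp", not "pulpS1…S4"). This is the view under
  which the packaged table reproduces the survey's organ totals
  exactly (221 root, 209 pulp, 203 leaf, 196 peel, 129 embryogenic,
  98 seedling).

The packaged FPKM table is integer-rounded as printed; counts that
depend on values between 0 and 0.5 (notably the all-samples class: 43
on the rounded table) differ from what unrounded data would give, and
are reported as computed rather than adjusted.

Paralog comparison reports Pearson correlation of log₂(FPKM+1)
profiles (pseudocount 1 bounds the influence of zeros) and the Jaccard
overlap of expressed-organ sets.

## Synthetic data

The generator's defaults mirror the observed family marginals: exon
counts drawn from the survey's histogram (mode 3), ~1% unplaced genes,
~10% motif carriers among retained genes, per-organ expression
probabilities equal to the survey's organ shares, breadth-class priors
(4.4% silent, 13.7% ubiquitous), log-normal FPKM (log-mean 1.5, σ 1).
Planted repeats are consensus copies at a configurable per-residue
mutation rate (default 0: the recovery benchmarks are defined on
noise-free families, with mutation sweeps as a separate stress
property). Clade structure: ancestors diverge from the shared
consensus at rate 0.3, members from their ancestor at 0.05 — clean
separation by construction. One master seed drives named substreams
(sequence / structure / expression / clades), so modules regenerate
independently and bundles are byte-identical per seed.

What passing the synthetic benchmarks does *not* show: recovery on
real proteins with genuinely diverged repeats (the noise-free benchmark
bounds only the bookkeeping, not the sensitivity of the profile), the
behaviour of center-star alignment on length-heterogeneous domains,
or robustness of clade assignment when reference sets are sparse or
mislabelled. The background residue model is uniform over the 20
amino acids; the spurious bHLH-motif probability per window is
(2/20)·(1/20)²·(2/20)·(1/20)·(1/20) ≈ 1.3 × 10⁻⁷, so spurious motif
hits in tests are expected to be absent at the simulated sizes, and
any that appear are logged, not suppressed.

## Problem sizes

The packaged analyses and tests run at deliberately modest sizes: the
default synthetic family has 45 genes (53-leaf trees, B = 100
bootstrap), the repeat-recovery benchmark uses 200 proteins, NJ
correctness uses 100 random 4–12-taxon additive matrices, and the
motif oracle uses 1,000 random 500-residue sequences. These sizes give
stable, reproducible metrics while keeping a full run in seconds to
minutes; all of them scale linearly (motif, scan) or polynomially
(alignment O(n²), NJ O(n³)) if larger studies are needed.
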