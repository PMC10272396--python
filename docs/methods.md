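# Methods

## Coordinate model

All analyses operate on gene *order*, not nucleotide coordinates. Every
protein-encoding gene (PEG) of a replicon is assigned an ordinal rank
1..n by position (for GFF3 input, CDS features sorted by start coordinate;
for the TSV dialect, explicit ordinals that must run 1..n without gaps), and
keeps only its coding strand and its functional class. Distances are ordinal
differences. This makes the statistics insensitive to gene length and
intergenic spacing: two "adjacent" genes (SSc = 1) may be separated by any
number of nucleotides, and a gene-rich island counts the same as a sparse one
of equal gene count. Genes on different replicons never pair; plasmids are
analyzed independently and contribute to genome totals.

Replicons are circular by default — the common case for complete bacterial
chromosomes — with distances wrapping across the origin; a per-replicon flag
selects linear behavior (then end genes have one-sided neighbors, and a
replicon's wrap pair is dropped). Both modes are first-class and covered by
the exhaustive small-genome tests, since input metadata rarely records
topology reliably.

## Classification

A gene's class derives from its protein-domain hits through a family map
(accession → family label + functional class). A gene is a GH gene iff at
least one hit maps to a GH-class accession; its transporter classes are the
set of MFS/ABC/PTS/SUS classes among its hits. A gene carrying both a GH and
a transporter domain keeps both flags: it is a GH gene for synteny purposes
and can serve as a transporter partner for *other* GH genes, but never for
itself. Accession version suffixes (`PF00128.15`) are always stripped before
lookup. Hits below `min_score` (default 25 bits, configurable — a
conservative general-purpose bit-score floor) are discarded at parse time.

The built-in map covers the ten most common bacterial GH domains
(PF00128/GH13, PF00232/GH1, PF00933/GH3, PF00150/GH5, PF01270/GH8,
PF01341/GH6, PF00331/GH10, PF00457/GH11, PF00704/GH18, PF00182/GH19) and the
four TonB-dependent-transporter domains that define the SUS class (PF00593
barrel, PF07715 plug, PF13715 NTE, PF07660 STN); a gene qualifies as SUS on
the core barrel or plug domain alone, without requiring a SusD partner. The
MFS, ABC and PTS entries ship as single canonical-domain placeholders
(PF07690, PF00005, PF02378/PF00358) and are meant to be extended through a
user map for serious annotation work; the map file is the single source of
truth and overrides defaults entry by entry.

## Synteny scores and clusters

For each gene of a class, SSc = min(ordinal distance to the previous
same-class gene, to the next one) within its replicon. A replicon with a
single class member yields an undefined SSc, reported as `NA` and counted as
unclustered in every fraction (denominators are always the total class-gene
count). Per-genome histograms N_SSc and F_SSc tally genes at SSc = 1..s_max
(default 20), with genes beyond s_max and undefined genes tracked separately
so the parts always sum to the total.

Clusters at threshold t (default 5, chosen to capture closely linked but
non-contiguous genes) are maximal chains in which every consecutive gap is
≤ t; singletons are size-1 clusters. On circular replicons the wrap gap can
join the last chain to the first, and a fully connected circle is a single
cluster. "Clustered" is a per-gene property (SSc ≤ t), so the clustered
fraction is monotone in t by construction.

## Orientation

Sequential same-class pairs are the unit of the codirectionality statistics:
a circular replicon with m ≥ 2 members contributes m pairs (including the
wrap pair), a linear one m − 1. The gap of a pair is exactly its SSc, so the
"clustered" restriction keeps pairs with gap ≤ 5. The observed codirectional
count k among n pairs is tested against Binomial(n, ½) with an exact
two-sided p-value by equal-tail doubling, p = min(1, 2·min(P[X ≤ k],
P[X ≥ k])); an exact test is used because n is small in most genomes, where
a normal approximation would misbehave.

## Randomization nulls

The null model is uniform placement: g class genes resampled without
replacement among N slots, preserving the replicon partition (each replicon
keeps its own N and g) when matched to a real genome. Per iteration the full
statistic set is recomputed through the same synteny code path as observed
genomes. Defaults are 5,000 iterations per condition. Empirical p-values use
the add-one rule, p = (1 + #{null ≥ observed}) / (1 + iterations), so no
reported p is exactly zero; with a discrete statistic ties make this slightly
conservative, which the test suite checks coarsely (mean p near but above
0.5 under the null, and no anti-conservative excess below nominal levels).

Two independent oracles guard the Monte-Carlo machinery: exhaustive
enumeration over all C(N, g) placements for tiny genomes, and the
hypergeometric closed form for the expected number of contiguous genes —
conditional on a focal gene's slot, both flanking slots are free with
probability (N−g)(N−g−1)/((N−1)(N−2)) on a circle, so
E[#SSc = 1] = g·(1 − that), with the two one-neighbor end slots handled
separately for linear replicons. Simulated means are required to sit within
four standard errors of these values.

Normality of a statistic's sampling distribution is summarized by the
Shapiro–Wilk test; samples above 5,000 values are subsampled (seeded) first
because the test's p-value is unreliable at huge n. In the high-GH-frequency
regime (e.g. 300 of 5,000 PEGs) the per-replicate mean SSc is approximately
normal (W ≥ 0.98). In the sparse regime (< 1% GH genes) the departure from
normality is asserted through the mean SSc's p-value (p < 0.01) and through
the per-bin adjacent-gene counts, whose near-degenerate discreteness drives
W far below 0.98; the W of the mean SSc itself stays above 0.98 even at the
sparsest condition on the grid, so the regime boundary is a property of
which statistic is examined, not of the threshold.

## Colocalization

For each GH gene and each transporter class, the minimum ordinal distance to
a gene of that class on the same replicon (wrap-aware on circles) is
recorded when ≤ 10 PEGs; equidistant candidates resolve to the upstream
partner. Strand is ignored. The genome summary reports the fraction of GH
genes with at least one partner (the per-gene denominator), per-class GH
counts, and the count of GH genes associated with more than one class. A
small-genome enumeration oracle checks the uniform-placement occupancy
probability 1 − C(N−1−2t, k)/C(N−1, k) exactly.

## Cohort statistics

Across genomes, GH count vs genome size is summarized by Pearson r (with
two-sided p) and the OLS slope of counts on PEGs. A response with zero
variance returns a degenerate-flagged zero instead of aborting a cohort run.
The variance of GH-gene clustering is decomposed by a linear model with
sequential (type-I) sums of squares in the fixed order genome size, GH
count, interaction — the natural reading of a single "% variance explained"
split that sums with a residual to 100% — via `statsmodels` `anova_lm`.
The response is the clustered-gene count by default, with any frequency
column usable through the `response` argument; exact collinearity among the
design columns is rejected up front with the offending terms named.
Group summaries report n, mean, and sd per taxon (sd is `NA` for singleton
groups).

## Synthetic genomes

The generator emulates the studied regimes: replicons of 1,000–15,000 PEGs
carrying 0.5–10% GH genes, either scattered uniformly or organized into
planted clusters. Clusters are planted as runs with within-cluster gaps
uniform on [gap_min, gap_max] (default 1..5, inside the clustering
threshold), placed by rejection sampling with a cap of 1,000 attempts;
remaining GH genes fill uniformly among free slots. Within a cluster each
sequential pair shares the strand with probability `codir_prob` (default
0.9, reflecting the strongly codirectional organization of real GH clusters);
background strands are Bernoulli(½) by default. Transporters of each class
are placed near a randomly chosen planted cluster (within 10 PEGs of its
edges) with probability `tr_coplacement_prob`, uniformly otherwise. Each
annotated gene receives one representative accession of its class, so
generated hit tables exercise the real annotation path, and emitted TSV
pairs round-trip exactly through the readers.

Two planted clusters can land within the clustering threshold of each other
and coalesce; the generator can return the planted layout so recovery tests
distinguish such chance merges from detection failures.

What the generator does *not* emulate: nucleotide sequence, gene length and
intergenic-distance variation, operon scaffolds or other local gene-order
correlation outside the planted clusters, multi-domain Pfam architectures,
and lineage-specific base composition. Passing tests therefore demonstrate
the correctness of the statistics and their null calibration on
order-reduced genomes, not the fidelity of any biological claim about real
genomes — on real data the null model's uniformity assumption is exactly the
hypothesis under test.

## Reporting conventions

Percentages in summaries are displayed truncated (floored) to one decimal —
e.g. 160/7,069 → "2.2%" — matching the convention of the worked summaries
the package reproduces; full-precision values are always kept in parallel
columns. Undefined values serialize as `NA` in TSV output. Pipeline runs are
deterministic under a master seed, with per-genome and per-condition streams
derived from it; reruns produce byte-identical tables.

## Problem sizes

The default test and acceptance workloads use 5,000-iteration randomizations
at the reference condition (5,000 PEGs, 300 GH genes), 200-replicate
calibration checks, and exhaustive enumeration for replicons of up to 8 PEGs
with up to 3 class genes — sizes at which the enumeration oracles are exact
and the Monte-Carlo standard errors are small compared to the tested
tolerances, while a full run stays in the tens of seconds on one core.

## Known limitations

- PEG ordinals are a proxy for physical position: insertions of non-coding
  features, pseudogenes, or annotation differences shift distances.
- The provisional MFS/ABC/PTS domain lists under-annotate those transporter
  classes until a curated map is supplied.
- No phylogenetic correction: cohort regressions treat genomes as
  independent, so lineage structure inflates apparent significance.
- No operon or regulon inference: codirectionality is a necessary, not
  sufficient, condition for co-transcription.
- Whether distances should wrap across the replicon origin is genuinely
  ambiguous for some assemblies; both behaviors are supported and reported,
  and the choice matters most for small replicons with few class genes.
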