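# ghsynteny

Bacteria that degrade polysaccharides rarely rely on a single enzyme: complete
carbohydrate deconstruction needs many glycoside hydrolases (GHs) acting
together, often alongside dedicated sugar transporters. In genomes such as
those of *Bacteroides*, these genes sit in physically clustered, codirectional
neighborhoods (polysaccharide utilization loci); in others they are scattered.
`ghsynteny` quantifies this *supragenic organization* of GH genes from ordered
gene tables and protein-domain hits, and asks whether the observed clustering
exceeds what uniform random gene placement would produce.

The package is aimed at comparative microbial genomicists who already have
per-genome gene calls (e.g. GFF3) and Pfam-style domain hits (e.g. hmmscan
`--domtblout`) and want reproducible neighborhood statistics across one genome
or a cohort.

## The statistics

Each protein-encoding gene (PEG) is reduced to its ordinal rank along its
replicon plus its coding strand. For a gene of interest, the **synteny score**

> SSc = min(distance in PEGs to the previous same-class gene,
>            distance to the next same-class gene)

is computed within the replicon (wrapping across the origin when the replicon
is circular). Contiguous genes have SSc = 1; a gene is *clustered* when
SSc ≤ 5, and maximal chains of genes whose consecutive gaps stay within the
threshold form clusters. On top of this primitive the package computes:

- **N_SSc / F_SSc** — the per-genome count/frequency histogram of GH genes at
  each SSc value (1..20 by default), and the clustered fraction at any
  threshold;
- **codirectionality** — the fraction of sequential GH-gene pairs on the same
  strand, overall and restricted to clustered pairs (gap ≤ 5), tested against
  Binomial(n, ½) with an exact equal-tail two-sided test;
- **randomization nulls** — for a genome with N PEGs and g GH genes, g slots
  are resampled uniformly per iteration (replicon partition preserved) and
  every statistic is recomputed, giving null bands, medians, and add-one
  empirical p-values. For the count of contiguous genes the null expectation
  has a hypergeometric closed form, E = g·(1 − (N−g)(N−g−1)/((N−1)(N−2))) on a
  circle, used as an independent cross-check;
- **GH:TR colocalization** — for each GH gene, the nearest transporter of each
  class (MFS, ABC, PTS, SUS/TBDT) within SSc ≤ 10, and the fraction of GH
  genes with at least one transporter partner;
- **cohort statistics** — Pearson r and OLS slope of GH count on genome size,
  and a sequential (type-I) variance decomposition of clustered-gene counts
  into genome-size, GH-count, and interaction terms;
- **synthetic genomes** — a generator that plants codirectional GH clusters
  and co-placed transporters with known parameters, so the whole pipeline is
  testable without downloads.

## Worked example

Generate a genome of 5,000 PEGs with 160 GH genes (20 planted clusters of 4,
90% codirectional, ABC/MFS transporters co-placed near clusters), then
summarize it against a 5,000-iteration matched null:

```python
import ghsynteny as ghs
from ghsynteny.synthetic_data import SynthSpec, generate_genome

spec = SynthSpec(
    n_pegs=5000, n_gh=160, cluster_count=20, cluster_size=4,
    gap_min=1, gap_max=3, codir_prob=0.9,
    tr_counts={"TR_ABC": 40, "TR_MFS": 30}, tr_coplacement_prob=0.7,
    genome_id="demo", seed=42,
)
genome = generate_genome(spec)
summary = ghs.summarize_genome(genome, null_iterations=5000, seed=42)
```

which prints, via the fields of `summary`:

```
demo: 5000 PEGs, 160 GH genes (3.2%)
clustered (SSc<=5): 101 genes, fraction 0.631
codirectional fraction, clustered pairs: 0.792 (binomial p = 6.54e-07)
colocalized with a transporter (SSc<=10): 0.588
matched null median clustered fraction: 0.275; empirical p = 2.00e-04
```

Read: 3.2% of the PEGs are GH genes; 63% of them are clustered, against a
median of 27.5% in 5,000 size-matched random genomes (empirical p = 2×10⁻⁴,
the add-one minimum at these iterations), so the planted organization is
recovered as strongly non-random. The clustered pairs are 79% codirectional
(close to the planted 90%, estimated from ~110 pairs), rejecting the 50%
binomial baseline. For real data, replace the generator with
`read_feature_table` / `read_domain_hits` / `annotate`, or run the `ghsynteny`
command-line tool (`simulate`, `annotate`, `synteny`, `orient`, `null`,
`coloc`, `cohort`, `render`, or `all` with a YAML config).

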