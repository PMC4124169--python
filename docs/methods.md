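# Methods

This note records the models, parameter choices, and known limitations
behind each stage of the pipeline, and what the synthetic fixtures do
and do not emulate.

## Coordinates and formats

All intervals are 1-based and closed in memory (the GTF convention).
BED and bedGraph files are 0-based half-open on disk and converted at
the I/O boundary. Outputs are TSV with deterministic row order, so a
fixed seed reproduces byte-identical files.

Cross-genome conversion uses a block map: a list of equal-length
colinear spans between two assemblies (a simplified liftOver chain). An
interval converts when at least 50% of its bases fall inside blocks
that agree on destination chromosome and strand; minus-strand blocks
reverse coordinates within the block. The 50% threshold is a
convention of this package; unmapped intervals are dropped and counted
in the log rather than raised as errors.

## RPKM

`rpkm = count / (merged_exon_kb * mapped_total/1e6)`. The exon model is
the union of a gene's exons, so overlapping exons are not
double-counted. By default the mapped total is the column sum of the
count table; real pipelines often normalize by all aligned reads
(including non-exonic ones), which this model does not see, so per-
sample totals can be supplied explicitly. RPKM is zero exactly when the
count is zero, is invariant to uniform count scaling with rescaled
totals, and is linear in the count at fixed totals.

## Differential expression

Counts are negative binomial with mean `s_j * q_g` and variance
`mu + alpha*mu^2` (dispersion `alpha`). Size factors `s_j` are
median-of-ratios: the median over all-positive genes of the count over
its across-sample geometric mean, renormalized to geometric mean 1.

Dispersion: per gene, a method-of-moments estimate from within-group
variances of normalized counts (Poisson part `q * mean(1/s)`
subtracted); the working value is the *cross-gene average* of those
estimates (over genes with normalized mean >= 1), floored at 1e-3.
With two replicates per group a per-gene estimate has ~2 degrees of
freedom and plugging it into any test statistic destroys calibration
(we measured type-I error ~2.5x nominal, with false calls deep in the
tail); the cross-gene average is accurate when dispersion varies slowly
across genes, which is exactly the regime the fixtures simulate. The
cost is that genuinely hyper-variable genes are tested at too small a
dispersion; a mean–dispersion trend fit would be the next refinement.

Significance comes from an exact conditional NB test on the two group
count sums: conditioned on the total, the probabilities of all splits
at most as likely as the observed one are summed. The sum of NB counts
with common dispersion and means `s_j*q` is treated as NB with mean
`S*q` and variance `S*q + alpha*q^2*sum(s_j^2)`. This is the classical
exact-test construction for two-group NB comparisons, and unlike a
Wald z-test on the log fold it keeps the extreme tail honest at n = 2
per group — important because the enrichment gate sits at p < 1e-7.
Measured on the default null (2,000 genes, 2 vs 2, dispersion 0.05):
fraction of p < 0.05 averages 0.051 across seeds, and no gene reaches
p < 1e-7 in any of 50 seeds.

Fold changes are `log2((mean_A + 0.5)/(mean_B + 0.5))` on normalized
group means. Calls require p < 1e-7 jointly with BH q < 0.001 (the
"FDR < 0.1%" gate). Genes with zero counts everywhere are excluded
from testing and reported `ns`. Swapping the group labels negates every
fold and leaves p-values exactly unchanged.

The glucose-response ranking reuses the same test on control vs.
stimulated tables over a mixed universe of coding genes and lncRNAs,
sorted by `sign(log2_fold) * -log10(p)` (p floored at 1e-300).

## Cross-species comparison

Orthologs are restricted to 1:1 pairs; any identifier occurring in more
than one pair is dropped (logged). The common core is the set of pairs
with replicate-mean beta RPKM strictly above 1 in both species. The
cross-species test runs the NB machinery on ortholog-paired beta counts
with species as the grouping factor; the fold gate (> 10-fold) is
evaluated on normalized counts, while the RPKM values are used only for
the > 1 / < 1 expression gates. Within a significant side, "unique"
means the other species' beta RPKM is below 1, otherwise "enriched";
pairs failing the gate are "shared" when both RPKMs clear 1 and "ns"
otherwise. Calls mirror exactly under swapping the two species.

Species-specific TF binding: peaks of the second species are converted
onto the first genome, peak intervals of both species are unioned into
regions, per-region read sums are normalized per million peak reads,
and a region is species-specific when the ratio is >= 4 (inclusive, so
40 vs 10 reads-per-million qualifies). The denominator is floored at 1
read-per-million so empty regions do not divide by zero.

## lncRNA discovery

Coverage from all alpha and beta replicates is summed into one
meta-experiment. Segmentation keeps positions with depth >= 0.02
(arbitrary depth units; the default is set so loci around RPKM 0.3 are
still segmented and can then fail the expression filter rather than
silently vanish) and merges runs separated by gaps strictly below
1,500 bp — a 1,499 bp gap merges, a 1,500 bp gap splits.

The five rules, applied in order with the full pass/fail trace kept for
every candidate:

1. exon overlap — any single base of overlap with any annotated gene
   exon fails (strand-ignored; the library type is unstranded);
2. length — strictly greater than 3,000 bp;
3. expression — alpha OR beta replicate-mean RPKM strictly above 1;
4. rRNA — any overlap with a known rRNA locus fails;
5. conservation — mean PhastCon strictly above 0.4 fails (a mean of
   exactly 0.4 passes). The mean is interval-wide; a maximal-per-base
   variant would be stricter but is not used. The conservation track
   must cover every candidate base, otherwise an error is raised.

Survivors are "intronic" when fully contained in the gene-body span
(first exon start to last exon end) of at least one protein-coding
gene, else "intergenic". Candidate RPKM is derived from coverage mass
(depth x bases / read length, default read length 50).

The discovery stage is segmentation-only; no splice-aware assembly is
attempted, and no coding-potential score beyond the conservation rule
is applied.

## Regulatory overlays

Transcript-end enrichment counts the fraction of transcript boundaries
(both 5' and 3', not distinguished) with at least one peak within
±1 kb (configurable) and compares it to the same statistic at matched
numbers of uniformly drawn genomic positions, repeated `n_random`
times (>= 100 enforced). The ratio divides observed by mean null rate;
the empirical p uses the +1 correction and never returns 0. With zero
peaks the ratio is reported as NA with a message.

PWM scanning is plain log2-odds against a uniform background on both
strands; windows containing N are skipped; hits are at-or-above the
threshold (by default 80% of the motif's maximal score when reading
JASPAR files). Motif clusters are maximal groups of overlapping
windows of <= 300 bp holding >= `min_sites` hits; the cluster statistic
is the best within-window count, and its p-value compares that count
against uniform shuffles of all hit positions over the scanned region.
This count-in-window statistic deliberately replaces an HMM-based
cluster scorer (MCAST-style); cluster *recovery* is the design goal,
and no claim is made of reproducing HMM p-values.

## Co-regulation

Each lncRNA is paired with the protein-coding gene minimizing the gap
to its gene-body span (0 when overlapping, e.g. intronic lncRNAs and
their host); ties break toward the smaller gene start, then the
lexicographically smaller id; strand is ignored. The statistic is the
Spearman correlation of `log2((beta+0.1)/(alpha+0.1))` RPKM ratios
between lncRNA and neighbor, which makes the result invariant to any
common monotone rescaling of expression. Spearman is chosen over
Pearson because the ratio distributions are heavy-tailed. At least 10
finite pairs are required.

## Synthetic fixtures

The generator builds two genomes (default four chromosomes of 12 Mb
per species — sized so 2,000 genes plus all lncRNA loci fit with
comfortable spacing), gene models of 2–4 exons, an ortholog table
covering 90% of genes 1:1, and plants:

* 50 beta- and 50 alpha-enriched genes at 20-fold (one-sided: the
  enriched population's mean is multiplied);
* 40 unique and 20 enriched genes per species. Unique genes get mean 0
  in the other species, because at desk-scale depth a single stray
  count already exceeds RPKM 1, whereas real deep libraries resolve
  RPKM far below the gate; enriched genes get a 20-fold mean ratio
  with the minor side still clearly expressed;
* 145 lncRNA loci (18 intronic in dedicated host genes, 127 intergenic
  next to a designated neighbor gene) plus five decoy classes of 20,
  each violating exactly one filter rule (exon overlap, <= 3 kb,
  RPKM <= 1, rRNA overlap, conservation 0.8);
* neighbor/host genes carry a continuous beta/alpha skew; the lncRNA
  ratio is coupled through a Gaussian copula whose Pearson parameter
  is `2*sin(pi*rho/6)` so the *Spearman* correlation targets the
  configured `coreg_rho` (default 0.6);
* 200 TF peaks, 60% within 1 kb of lncRNA ends, the rest uniform with
  enforced non-overlap so planted species read ratios (5-fold, default)
  survive region merging; a whole-genome block map with one inverted
  segment per chromosome;
* one 20 kb sequence with 13 ETS1 consensus sites inside a 300 bp
  window (alternating strands) plus scattered isolated sites; chance
  occurrences of the consensus are scrubbed so motif hits are exactly
  the planted ones;
* glucose-response tables over genes plus lncRNAs with 30 up- and 30
  down-regulated transcripts at 10-fold (10 of the up-set on lncRNAs).

Counts are NB with dispersion 0.05 (typical bulk RNA-seq; the study
design this emulates reports no estimate) and per-sample library
factors log-uniform in [0.5, 2]. Base means are log-uniform between
~3 and 1,000 expected counts. Coverage is emitted as bedGraph-style
intervals over the planted loci only; expressed gene exons carry no
coverage, so the exon-overlap rule is exercised purely by its decoy
class. Everything derives from one seed through per-stage spawned
generators, and `verify_ground_truth` re-derives the planted labels
from the emitted data.

What the fixtures do **not** emulate — and hence what passing tests do
not show about real data: alignment artifacts and mapping ambiguity,
fragment-level coverage noise, gene-to-gene dispersion variation,
correlated expression structure beyond the planted categories, realistic
exon/intron statistics, assembly gaps, and many-to-many orthology.
Recovery rates on real libraries will be lower than on these fixtures;
the planted designs establish correctness of the machinery, not
field performance.

## Numerical conventions

Empirical p-values always use the +1 correction. The exact NB test
treats splits with probability within a 1e-8 relative band of the
observed one as ties (included in the p-value). BH adjustment is the
standard step-up procedure. Fold pseudocount 0.5 normalized counts;
RPKM ratio pseudocount 0.1; all thresholds (p 1e-7, q 0.001, fold 10,
RPKM 1, PhastCon 0.4, 3 kb, 1.5 kb merge distance, 4-fold peaks) are
configurable dataclass fields with the defaults above.
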