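# isletkit

Analysis pipeline for FACS-purified pancreatic islet transcriptomes:
differential expression between beta and alpha cells, cross-species
(mouse vs. human) comparison of the beta-cell transcriptome, rule-based
discovery of novel long non-coding RNAs (lncRNAs), regulatory overlays
(TF-peak enrichment at transcript ends, species-specific differential
binding, motif-cluster detection), and lncRNA/neighbor-gene
co-regulation. The package ships a synthetic-data generator that plants
ground truth for every stage, so the whole pipeline is testable without
any external download.

It is written for computational biologists who want a small, fully
deterministic, end-to-end re-implementation of this analysis style —
either to run on their own count/coverage/peak tables or to use the
planted-truth fixtures as a benchmark harness.

## Methods at a glance

* **RPKM** — `rpkm_g = count_g / (L_g/10^3 · N/10^6)` with `L_g` the
  union length of the gene's exons ("exon model") and `N` the sample's
  mapped-read total.
* **Differential expression** — counts are modeled as negative binomial,
  `Var = μ + αμ²`. Size factors use the median-of-ratios estimator;
  dispersion is a cross-gene average of per-gene moment estimates; the
  per-gene p-value comes from an exact conditional NB test on the group
  count sums. Enrichment calls require `p < 10⁻⁷` and BH `q < 0.001`.
* **Cross-species classification** — 1:1 orthologs with beta RPKM > 1 in
  both species form the common core; a gene is species-specific when the
  cross-species NB test gives > 10-fold enrichment at the same joint
  significance gate, and "unique" vs. "enriched" splits on whether the
  other species' beta RPKM is below 1.
* **lncRNA discovery** — pooled alpha+beta coverage is segmented into
  maximal dense runs (gaps < 1,500 bp merged), then filtered by five
  rules: no exon overlap, length > 3 kb, alpha or beta RPKM > 1, no rRNA
  overlap, mean PhastCon ≤ 0.4. Survivors are classed intronic or
  intergenic.
* **Regulatory overlays** — empirical enrichment of TF ChIP peaks within
  ±1 kb of transcript ends against uniform random positions; log-odds
  PWM scanning on both strands; motif clusters as ≥ k hits in a ≤ 300 bp
  window with shuffle p-values; species-specific peaks as ≥ 4-fold
  normalized-read differences after liftOver-style coordinate
  conversion.
* **Co-regulation** — Spearman correlation of `log2((beta RPKM + 0.1) /
  (alpha RPKM + 0.1))` between each lncRNA and its nearest
  protein-coding gene.

See `docs/methods.md` for assumptions, parameter defaults, and the
design of the synthetic fixtures.

## Worked example

Generate a small fixture and run the pipeline (the `--seed` makes every
output byte-reproducible):

```bash
isletkit --seed 7 --out-dir demo simulate --preset small
isletkit --seed 7 --out-dir demo de \
    --counts demo/counts_mouse.tsv \
    --group-a beta_1,beta_2 --group-b alpha_1,alpha_2 \
    --label-a beta --label-b alpha
# 45 of 300 genes called enriched
isletkit --seed 7 --out-dir demo lncdiscover \
    --coverage alpha=demo/coverage_alpha.bedgraph \
    --coverage beta=demo/coverage_beta.bedgraph \
    --gtf demo/mouse.gtf --rrna demo/rrna.bed \
    --conservation demo/conservation.tsv \
    --total alpha=2000000 --total beta=2000000
# 16 novel lncRNAs (4 intronic, 12 intergenic); 15 candidates rejected
isletkit --seed 7 --out-dir demo regulatory \
    --transcripts demo/lnc_survivors.tsv --peaks demo/peaks_mouse.tsv \
    --chrom-sizes demo/mouse.chrom.sizes \
    --fasta demo/cluster_locus.fa --pwm demo/motifs.jaspar --n-random 200
# end enrichment ratio 38.2 (p = 0.00498)
# 1 motif clusters detected
```

The DE call count (45 of 300) covers the 30 planted 20-fold enriched
genes plus the genes the generator deliberately skews for the
co-regulation analysis. The lncRNA stage recovers exactly the planted
16 transcripts while rejecting all 15 decoys, each at the filter rule it
was built to violate. The end-enrichment ratio of ~38 reflects that 60%
of the simulated TF peaks were planted within 1 kb of transcript ends;
its p-value is the empirical floor `1/(1 + n_random)`. The single motif
cluster is the planted run of 13 ETS1 consensus sites inside a 300 bp
window.

Other subcommands: `quantify` (RPKM tables), `xspecies` (common core
and species-specificity calls), `coreg` (nearest-gene pairing and the
co-regulation correlation).

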