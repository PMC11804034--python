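# bilecirc

Toolkit for profiling **bile cell-free extrachromosomal circular DNA
(bcf-eccDNA)** from rolling-circle-amplified nanopore concatemer reads, and
for turning that profile into a liquid-biopsy readout for malignant biliary
strictures. It is aimed at computational biologists who want a transparent,
fully testable re-implementation of the analysis chain — from circle calling
through diagnostic evaluation — together with a synthetic-data generator
that reproduces the statistical structure of published bile eccDNA cohorts,
so every stage runs and is validated without any sequencing download.

## What it does

- **Synthetic study world** (`bilecirc.synthetic`) — a desk-scale genome
  with gene models, promoters, CpG islands, super-enhancers (each with a
  closest active gene), miRNAs and miRNA clusters; two-group eccDNA cohorts
  whose size distributions, genomic origin models and marker-gene
  enrichment mirror reported bile profiles; and phi29-style concatemer
  reads with per-pass substitution/indel errors plus exact truth tables.
- **Circle calling** (`bilecirc.caller`) — reconstructs eccDNA from
  read-to-reference alignments (PAF, or SAM via pysam). A concatemer read
  aligns as a periodic chain of reference segments; the caller detects the
  minimal repeating unit with endpoint tolerance and calls a circle when
  the read completes **≥ 2 full passes**. Multi-read evidence is merged by
  reciprocal overlap and a per-position majority vote across passes yields
  a consensus sequence.
- **Landscape statistics** (`bilecirc.landscape`) — eccDNA count per mapped
  read, cumulative size curves, KDE size-peak detection, length-bin group
  comparisons (t test or rank-sum after a Shapiro–Wilk gate), chromosome
  origin fractions normalized per Mb, and 1-Mb window coverage tracks.
- **Class annotation** (`bilecirc.annotation`) — element labels by priority
  (promoter > exon > intron > UTR > CpG > intergenic), eccGene (≥ 1 bp
  exon/intron overlap), eccEnhancer / eccMIR / eccMIR-cluster (feature
  fully contained in one segment), group-specific feature sets, and
  oncogene / tumor-suppressor flags.
- **Differential abundance** (`bilecirc.differential`) — gene × sample
  count matrix and a negative-binomial exact test (library-size
  normalization, common method-of-moments dispersion, conditional
  two-sided test on pooled group sums) with BH adjustment and the
  fold ≥ 2 / padj < 0.05 filter.
- **Diagnostics** (`bilecirc.diagnostics`) — the marker **proportion
  statistic** (percent of a sample's circles carrying a marker gene),
  rank-formulation ROC/AUC, stratified percentile bootstrap CI
  (B = 2000), Youden-index cutoff, validation-cohort accuracy, and
  logistic marker combination (including serum CEA/CA19-9).
- **Variants** (`bilecirc.variants`) — multi-pass consensus SNV calling on
  circles, `g.<REF><pos><ALT>` descriptor parsing, COSMIC-style tiering
  (tiers 1–3 = cancer-related), VCF 4.2 output.
- **GALA design** (`bilecirc.gala`) — in-silico Gibson-assembly design of
  large multi-region circles: PCR fragments with shared 20-bp ends, the
  split-reversed linear dsDNA pair, in-silico assembly and junction
  verification.

The `bilecirc` command line exposes the pipeline
(`simulate → call → landscape → annotate → diff → diagnose → variants`)
with per-stage manifests and byte-reproducible reruns.

## The statistic at the core

For sample *s* with eccDNA set *E(s)* and marker gene *g*, the diagnostic
score is the proportion

  p(s, g) = 100 · |{e ∈ E(s) : e overlaps g}| / |E(s)|  (percent)

Cancer status is called when p(s, g) ≥ c\*, where c\* maximizes Youden's
J = sensitivity + specificity − 1 on the training cohort. AUC is the
Mann–Whitney rank statistic; its CI is a stratified percentile bootstrap
over 2000 replicates. Differential eccGenes use the classic NB exact test:
counts scaled to the geometric-mean library, common dispersion φ estimated
by method of moments, and the two-sided conditional probability of the
observed split of pooled group sums (φ → 0 reduces to the binomial exact
test).

## Worked example

```python
from bilecirc import (GenomeSpec, CohortSpec, simulate_genome,
                      simulate_cohort, find_eccgenes, marker_proportion,
                      roc_auc, youden_cutoff)

genome = simulate_genome(GenomeSpec(), seed=1)          # 2 x 1 Mb world
spec = CohortSpec()                                      # 17 + 11 samples
cohort = simulate_cohort(genome, spec, seed=11)          # ~10k circles each
hits = {p.sample_id: find_eccgenes(p.eccdna, genome.bundle) for p in cohort}
labels = [p.group for p in cohort]
scores = [marker_proportion(p, "LINC00598", hits[p.sample_id])
          for p in cohort]
print(f"AUC = {roc_auc(scores, labels):.3f}")
cutoff, j, sens, spec_ = youden_cutoff(scores, labels)
print(f"cutoff = {cutoff:.4f}%  J = {j:.2f}")
```

Output:

```
AUC = 0.995
cutoff = 0.0362%  J = 0.94
```

The cancer group carries the marker on ~0.08% of circles versus ~0.008% in
the noncancer group (the configured eight-fold enrichment over a 0.01%
baseline), so the proportion statistic separates the groups almost
perfectly and the Youden cutoff lands between the two score clouds — the
same order of magnitude as published per-marker cutoffs in bile cohorts.

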