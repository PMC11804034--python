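# Methods

This note documents the models, parameter choices and numerical decisions
behind `bilecirc`, and what the synthetic test bed does and does not show
about real bile sequencing data.

## Synthetic study world

### Genome and feature catalog

The generator builds a small reference (default two chromosomes of 1 Mb;
chromosome lengths are constrained to 100 kb–5 Mb) with i.i.d. bases at a
configurable GC fraction (default 0.41). Feature placement is seeded and
non-overlapping within a class: genes (default 40/Mb, 2–8 kb) carry 2–6
exons anchored at both gene ends with intron gaps in between; UTR stubs sit
at each gene end; promoters are TSS ± 1 kb (also the fallback applied when
real-data mode supplies no promoter track). CpG islands, super-enhancers
(each annotated with the nearest gene midpoint as its "closest active
gene") and miRNAs are placed independently of genes, as in real annotation
tracks; two miRNA clusters of 2–4 members each are laid out so the cluster
interval contains every member. A request whose footprint cannot fit with
~5% breathing room fails with an explicit density error rather than
degrading placement quality.

A small lookup table of known somatic sites (chrom, 1-based position,
ref/alt read from the actual genome sequence, tier ∈ {1, 2, 3, other},
frequency) stands in for a mutation-significance database; it is generated
with the genome so joins are exact.

### Circle size mixtures

Cancer circle sizes follow a six-component Gaussian mixture at
200/380/560/740/950/1150 bp (sd 40 bp; weights 0.30/0.22/0.16/0.12/
0.08/0.05) plus a 6% uniform background on (50, 2000] and a 1% tail uniform
on (2000, 10000]. The noncancer profile is a single Gaussian at 170 bp
(sd 60, weight 0.92) with a 7% background and the same 1% tail. Draws below
the 50-bp library cutoff are redrawn *within their component*, preserving
the weights; lengths are floored to integers. Two consequences worth
noting:

- the sub-2-kb mass is **exactly 0.99** in both groups by construction, so
  an empirical estimate at n = 50,000 scatters symmetrically around 99%
  (SE ≈ 0.044%); checks of the "~99% below 2 kb" property are therefore
  made at the printed integer precision rather than as a strict empirical
  inequality;
- the tail's upper bound (10 kb) is a desk-scale choice; real bile eccDNA
  extends further but contributes almost nothing below 2 kb where all
  statistics of interest live.

### Origin models and marker enrichment

Cancer circles are placed uniformly over the genome (length-weighted
chromosome choice); noncancer circles send a fraction h = 0.6 to 20 fixed
hotspot loci (Gaussian spread 5 kb) and the rest to the uniform model,
emulating locus preference. About 5% of circles are two-segment chimeras
(split point uniform, each part ≥ 50 bp) so multi-region calling is
exercised; no rate is established for real bile data, this is a coverage
choice.

Marker enrichment is explicit rather than emergent: per marker gene, a
circle overlaps the marker with probability `marker_baseline` (default
1e-4, i.e. 0.01% of circles) in noncancer and `fold_change ×
marker_baseline` (default fold 8) in cancer; all other circles are redrawn
away from marker genes. The default baseline puts per-sample scores on the
same order as published per-marker cutoffs (hundredths of a percent) while
remaining detectable at the default depth of ~10,000 circles per sample.
At that depth the expected carrier counts are ≈ 1 (noncancer) versus ≈ 8
(cancer) per sample, which yields single-marker AUCs around 0.95–1.0 —
the "generator contract" the diagnostic tests check. Serum CEA and CA19-9
are drawn from lognormals whose means differ by ≈ 0.36 σ, i.e. AUC ≈ 0.6
each (weak standalone markers, useful only in combination).

Cohort sizes default to the study design: 17 cancer + 11 noncancer for
training and 9 + 3 for validation. Per-sample circle counts are negative
binomial (mean 10,000, dispersion 0.05); mapped-read counts are a Poisson
proxy at 20 reads per circle, used only by the count-per-read statistic.

### Read model

Each circle receives 1 + Poisson(5) reads; each read makes
Geometric(p = 0.4) ≥ 1 passes around the circle from a uniform start
offset, with context-free substitutions (3%) and insertions/deletions (1%
each) applied independently per base and per pass. The reads-per-circle
default matters for the caller contract: the probability that *no* read of
a circle reaches two passes is ≈ 2%, which bounds achievable recall at
≈ 0.98. The simulator emits an exact truth PAF whose blocks are merged
whenever contiguous on both read and reference (what a real aligner would
report); `perturb_paf` adds uniform endpoint jitter (tests use ≤ 10 bp) to
emulate alignment noise. Homopolymer-biased errors, basecaller artifacts
and chimeric library molecules are *not* modeled, so passing tests bound
behavior under clean concatemer structure, not under every nanopore
pathology; real-data mode consumes external minimap2 PAF (or SAM).

## Circle calling

Alignments are grouped per read and sorted by read position; segments
covering essentially the same read interval (> 50% of the shorter) keep
only the higher identity. Unit detection clusters chain segments into
reference intervals with 20 bp endpoint slack — a truncated copy produced
by the rotation split clusters with its full-length counterpart — and
requires the cluster-id sequence to be periodic with the cluster count as
period. Cluster extents are per-endpoint **medians over full-length
members** (taking the widest member instead would grow outward with every
jittered read). The pass count is ⌊covered/unit + 0.05⌋, i.e. a traversal
counts once ≥ 95% of the unit length is covered in order; reads that
repeat but never complete two traversals (e.g. 1.8 passes) are not called.
Calls require ≥ 2 passes.

Per-read candidates merge when segment counts match and every canonical
segment pair either overlaps reciprocally by ≥ 90% **or** agrees within
the 20-bp endpoint tolerance; merging iterates to a fixpoint because
medians move as groups grow. The tolerance arm exists because reciprocal
overlap alone cannot absorb ±10 bp jitter on circles shorter than
~200 bp, which would split small circles into duplicate records. Both
knobs (tolerance, coverage fraction) are config-exposed. Circles are
reported in canonical rotation (lexicographically smallest segment first);
predominantly reverse-strand chains are normalized by reversing the cycle
and flipping strands.

Consensus uses the read with the most passes: the first pass is the
backbone, the others are globally aligned to it (edlib) and vote per
backbone position, with majority insertions recovering backbone deletions
and ties resolved toward the backbone. The result is rotated to the
canonical circle start using the read's phase. At the default error rates
the consensus error is roughly half the raw read error; it is not
reference-free-polish quality, which is fine for its purpose (substitution
calling).

Cohort downsampling retains the minimum mapped-read count per sample,
sampling without replacement over sorted read ids under a named seed, and
recalls circles from the retained reads only.

## Landscape statistics

Size peaks come from a Gaussian-kernel density (bandwidth 25 bp, evaluated
on a bandwidth/10 grid, nearest padding at the range boundaries so a flat
density stays flat) with peaks at local maxima of prominence ≥ 5% of the
global maximum. Both knobs are config-exposed; with 50,000 draws from the
default cancer mixture the detector reports exactly the six configured
peaks within a few bp. Prominence thresholds of this kind are noise-limited:
a genuinely flat density needs several hundred thousand draws before KDE
sampling noise drops safely below the 5% floor.

Group comparisons use a two-tailed unpaired t test when both groups pass
Shapiro–Wilk at α = 0.05, otherwise the Mann–Whitney rank-sum test; a
paired signed-rank variant exists but is not the default, since the cohort
groups are unpaired. Raw p values are reported with BH-adjusted values
alongside. Chromosome fractions are densities per Mb renormalized to sum
to 1 per sample; window coverage sums overlap bp in 1-Mb tiles (last tile
short) and normalizes each sample to mean 1 over its covered windows
before taking the cross-sample median — the normalization constant is a
package decision, as is the covered-windows denominator.

## Annotation

Element labels take the highest-priority class overlapping any segment by
≥ 1 bp (promoter > exon > intron > UTR > CpG > intergenic; the order is
configurable since annotator conventions differ). eccGene requires ≥ 1 bp
overlap with an exon or intron — promoter-only overlap does not qualify.
"Intact" classes (eccEnhancer, eccMIR, eccMIR cluster) require the feature
interval to be contained in a *single* segment; a feature reconstituted
across the circular junction is not counted by default, with
`allow_junction_spanning` enabling the permissive reading for
reference-contiguous junctions. Interval queries run on interval trees and
are tested against quadratic brute-force oracles.

## Differential abundance

Counts are eccDNA records per gene (a multi-gene record increments each
gene; fractional splitting is available), scaled to the geometric-mean
library and rounded. Library sizes should be the per-sample total eccDNA
counts; the column-sum fallback is composition-sensitive when many genes
shift, the classic motivation for TMM — which this package deliberately
does not implement. A single common dispersion is estimated by pooled
method of moments within groups (Σ(v − m)/Σm², clipped at 0); there is no
tagwise shrinkage. The test is the conditional exact test on pooled group
sums: the sum of n i.i.d. NB(μ, φ) counts is NB(nμ, φ/n), and the
two-sided p value sums the probabilities of all splits no more likely than
the observed one. With φ = 0 this is exactly the two-sided binomial test,
which the suite verifies by enumeration. The reported filter is fold ≥ 2
(inclusive) and BH-adjusted p < 0.05 (strict). For real cohorts the
exported count matrix can be fed to edgeR directly.

## Diagnostics

AUC uses midrank tie handling; the ROC is computed at every distinct
threshold with positive = score ≥ threshold. The bootstrap CI is a
stratified (within-class) percentile interval over B = 2000 replicates
under a named seed, bit-reproducible; a class with one sample flags the
interval degenerate. The Youden cutoff scans midpoints of adjacent
distinct scores plus sentinels, breaking ties toward higher specificity,
and is applied inclusively (≥ c\* calls cancer). Markers separating
inversely have their sign flipped with a log message. Combination fits an
(effectively unpenalized) bivariate logistic model on standardized inputs
— proportions log10-transformed with a 1e-4 pseudo-count, serum values on
their measured scale — and falls back to a rank-average when the fit
degenerates. Note the fitted combination maximizes likelihood, not AUC, so
its training AUC can sit marginally (≲ 0.02 here) below the best single
marker on unfavorable samples.

## Variants

Every pass of every supporting read is globally aligned to the
rotation-phased reference unit, giving a per-pass base per reference
position; a site is called when ≥ 2 reads each show the same alternative
base in ≥ 80% of their passes. This exploits the within-read redundancy of
rolling-circle molecules: sequencing errors are independent across passes
while a true molecular variant appears in all of them. Substitutions only;
positions are 0-based internally and 1-based in VCF and `g.<REF><pos><ALT>`
descriptors. Tiers 1–3 of the lookup table count as cancer-related;
"other" and unmatched sites never do. A ±150 bp reference window around
each site supports downstream primer design; no thermodynamics are
modeled.

## GALA design

Fragment i spans target segment i plus the first 20 bp of segment i+1
(cyclically), so adjacent fragments share exact 20-bp ends; the overlap is
appended from the downstream segment rather than split across the junction
(either is valid homology; the choice is config-exposed). The design fails
loudly if any homology end occurs at more than one junction, since greedy
assembly would then be ambiguous. The split-reversed pair consists of the
circle linearized at 0 and at ⌊L/2⌋ — each molecule's ends anneal to the
other's interior, so ligation reconstitutes the circle; the symmetric
split maximizes that annealing length. Junction verification anchors the
assembly's rotation on segment-interior probes (doubled-string search) and
compares the 40-bp window across each breakpoint exactly.

## Pipeline and problem sizes

All randomness flows from named seeds; reruns with the same config produce
byte-identical outputs and per-stage manifests (input hash + output file
hashes) let unchanged stages skip rewriting. The default test-bed sizes —
2 Mb genome, ~10,000 circles per sample in truth-set statistics, hundreds
of circles with full reads in caller-level tests, 50,000 draws for size
statistics — were chosen so the whole suite exercises every stage at
statistically meaningful depth while remaining comfortable on a laptop
core. Truth-set mode (statistics computed on simulated circles directly)
and read mode (simulate reads, call, then compute) are both first-class;
read mode at full cohort depth is possible but unnecessary for the
contracts tested here.

## Known limitations

- The error model is context-free; nanopore homopolymer behavior, adapter
  chimeras and basecaller-specific artifacts are out of scope.
- The NB exact test is a behavioral approximation of the classic edgeR
  route (no TMM, no tagwise empirical Bayes); published differential gene
  counts from real cohorts are not expected to reproduce here.
- Real-cohort AUCs and cutoffs depend on the deposited sequencing data;
  the diagnostic numbers computed here validate the framework on the
  generator's configured enrichment, not the clinical result.
- The toy exact k-mer aligner exists only to exercise error-free synthetic
  reads end to end; real data should be aligned with minimap2.
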