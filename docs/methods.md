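# Methods

## Measurement model

Each sample is typed twice on a two-channel array: genomic DNA (gDNA) and
reverse-transcribed RNA (cDNA). At a biallelic SNP the two channels report
fluorescence x (allele A) and y (allele B); the allele fraction is
f = x/(x+y). In gDNA a heterozygote carries the alleles 1:1, so its gDNA
fraction is an internal standard that absorbs probe- and sequence-context
bias; in cDNA the fraction reflects the allelic balance of transcription.
The per-SNP ASE level of a heterozygous SNP in one sample is

    ASE = f_cDNA(hap1) − f_gDNA(hap1)

with both fractions oriented to the allele carried on haplotype 1, so that
SNPs phased onto the same haplotype agree in sign across a region. A region
without allelic imbalance has ASE ≈ 0; with gDNA fraction at 0.5 the ASE is
bounded by ±0.5.

Phased haplotypes are an input (the package never re-phases); orientation is
taken from the haplotype matrix as given.

## Normalization

The channel gains drift with signal intensity (dye bias), so raw het-gDNA
fractions trend away from 0.5 as a function of total signal. The correction:

1. Pool all data points of one template (gDNA or cDNA). The fit is
   restricted to points whose gDNA call is heterozygous: at those points each
   channel's expected signal is gain × total/2, so the two channels' medians
   are symmetric by construction and the genotype mix of the cohort cannot
   leak into the gain estimate.
2. Split the points into equal-count bins on log10 of the summed signal
   t = x + y (default 100 bins; `norm.n_bins`).
3. Per channel, take the median signal in each bin and fit a quadratic in
   log10(t) to log10(median) by least squares. Fitting the log-scale response
   makes the identity component of the median curve exactly linear, so the
   quadratic's curvature tracks only the gain drift; a raw-scale quadratic
   cannot follow the exponential trend over the ~1.5 decades of signal the
   arrays span and misses the gain by up to ~13% in the tail bins.
4. Adjust each point by dividing each channel by its predicted typical
   intensity at the point's own total:

       f_adj = (x/p̂_x(t)) / (x/p̂_x(t) + y/p̂_y(t)).

Exact properties: swapping the channels (with their models) maps f → 1−f;
identical models make the adjustment a no-op; x+y = 0 yields a missing
value, never 0.5. Predictions are floored at the 1st percentile of the raw
signals so the division cannot blow up on dim outliers. This construction is
a reconstruction of the normalization contract this assay family uses (binned medians of
the two colors, quadratic regression, prediction from log10 of the raw
signal); no closed-form reference equations were available, and the scheme
here is validated by its measurable contract — on simulated data with a
multiplicative gain g(t) = 1 + 0.3·log10(t)/4 on one channel, the fitted
ratio p̂_x/p̂_y recovers g within 2% at the bin centers, and the mean
adjusted het-gDNA fraction returns to 0.50 ± 0.01 in every intensity decile.

Raw fractions are retained for diagnostics (`normalization.raw_fraction`).

## QC

Order: SNP call-rate filter (non-missing fraction ≥ 0.99, inclusive), then
sample call rate (≥ 0.98) computed on the retained SNPs, then Hardy–Weinberg
on the retained matrix (plain 1-df χ² without continuity correction, allele
frequencies estimated from the same counts; removal at p < 10⁻⁶; a
monomorphic SNP is assigned χ² = 0, p = 1), then the contamination flag:
samples whose cDNA call rate is strictly greater than 0.40 are removed —
genomic DNA contaminating an RNA template makes heterozygous calls succeed
that pure cDNA would fail. The chain is idempotent. QC retention is applied
before the normalization fit so flagged samples and SNPs do not influence
the gain models.

## Window ASE and filters

An informative SNP is heterozygous in gDNA in ≥ 1 retained sample with
non-missing cDNA intensity there. A region is analyzable when ≥ 3 distinct
SNP positions are informative region-wide (not per sample — a sample then
contributes with however many het SNPs it has, ≥ 1) and its mean summed raw
cDNA signal over SNPs and samples is ≥ 1000 fluorescence units (inclusive).
The ≥ 3-SNP rule could also be read per sample; region-level was chosen
because informativeness describes the region's SNP content; a per-sample
rule would make the analyzable region set sample-dependent. Per sample, the window ASE is the arithmetic mean of its
oriented per-SNP ASE levels; samples without a het SNP in the region are
missing, not zero.

## Association test

For a window and a candidate SNP within ±250 kb (1-based inclusive
boundaries, SNPs inside the region included), each sample with both a window
ASE and a non-missing phased genotype enters with code

    hom (A|A, B|B) → 0,  A|B → +1,  B|A → −1.

Homozygotes at the candidate have no expected imbalance; heterozygotes
split into two groups whose ASE signs are set by phasing, so a real cis
effect appears as opposite means in the +1 and −1 groups. Ordinary least
squares of ASE on the code gives the slope (the het-group ASE magnitude) and
a two-sided t-test with n−2 df. Degenerate cases: constant codes → test
skipped; zero residuals with nonzero slope → p reported as the smallest
positive double; all-zero ASE → slope 0, p = 1. Coding het groups as ±1
rather than per-group dummies reproduces the described sign behaviour with a
single interpretable parameter; the choice is configurable nowhere because
the slope threshold is defined on this scale.

Significance requires p < 10⁻⁶, |slope| ≥ 0.05 and ≥ 4 samples in each of
AB, BA and the pooled homozygote class (the conservative reading of "four
data points per allele combination"; `assoc.min_per_class`). The slope
threshold corresponds to a 20% expression difference between alleles: with
fractions 0.5 ± s the relative difference is 400·s percent. The p cut-off is
the method's fixed default; `association.ld_pruned_test_count` (greedy pruning at
r² > 0.9) lets users re-derive an effective test count but never changes the
default.

LD is the squared haplotype correlation r² = D²/(p_A q_A p_B q_B), computed
on the provided haplotypes; reported "LD" values are interpreted as r².

## Enhancer enrichment

Within one histone mark, replicate peak sets are reconciled: peaks with
MACS-style p > 10⁻⁵ are dropped; a peak is supported by a replicate if some
peak there overlaps it by strictly more than 50% of the shorter peak's
length (the symmetric, stricter denominator; the focal replicate counts as
support, matching "two out of four overlapping peaks"); peaks with support
≥ 2 are kept and merged. Fold enrichment compares the in-peak fraction of
significant cis-rSNPs against that of clearly non-significant SNPs
(association p > 0.5); a SNP is "in" a peak when its 1-based position,
converted to 0-based, lies in the half-open interval. Significance is the
standard two-sided Fisher's exact test (sum of margin-fixed tables no more
probable than the observed one). Flanks extend peaks ±2.5 kb, clipped at 0
and merged.

## Co-expression and classification

For each lncRNA window with a cis-rSNP, the most significant SNP defines
three genotype groups (AA, pooled AB/BA, BB → 0/1/2); the nearest
protein-coding gene's expression — per-sample mean of summed raw cDNA
signals over the gene's informative SNPs, raw to match the total-expression
definition — is regressed on the code. Pairs passing Benjamini–Hochberg at
q = 0.10 are classified: `co_regulated` if the gene's own ASE association
with the same SNP has p < 10⁻⁶; `lnc_only` if that test exists but fails the
cut-off; `unknown` if the gene has no passing ASE window with an association
for that SNP (which requires the SNP within ±250 kb of the gene). Nearest =
minimal boundary distance on the same chromosome, ties to the smaller gene
start. The three categories partition the FDR-passing pairs.

## GWAS overlap

A catalog SNP overlaps a region's regulation directly (it is itself a
significant cis-rSNP there, recorded with r² = 1) or as an LD proxy (some
significant cis-rSNP of the region has r² ≥ 0.8 with it; 0.8 is the
conventional proxy bound and configurable). Catalog SNPs absent from the
haplotype panel are skipped for the proxy search. Each overlap is annotated
with enhancer context (in-peak, ±2.5 kb flank, none) using the same interval
predicate as the enrichment module. Immune-trait over-representation is a
two-sided Fisher test on unique catalog SNPs, overlapped × immune; the
immune flag is an input column, not inferred.

## Synthetic data generator

The generator's defaults are the emulated study conditions, fixed once, not
tuning knobs:

- 188 samples; 300 regions of 20 kb with 5 on-array SNPs each, 10 flanking
  candidate SNPs in the ±250 kb window (kept out of transcribed intervals),
  and a 20 kb protein-coding neighbour 50 kb away (300 kb for pairs meant to
  be non-evaluable).
- Haplotypes: allele-B frequency from MAF ~ U(0.1, 0.5) with the B label
  assigned to the minor or major allele with equal probability (so pooled
  channel statistics are label-symmetric); within a region's SNP block a
  latent AR(ρ = 0.6) Gaussian thresholded at the frequency quantile gives
  LD; genotypes are random haplotype pairs, hence Hardy–Weinberg holds by
  construction. Phasing truth is exported exactly (optional switch-error
  rate for robustness tests).
- Intensities: per-SNP totals are lognormal, median ≈ 3200 fluorescence
  units — the scale of expressed intergenic lncRNA regions — with per-region
  expression scatter (log10 sd 0.35) sized so roughly a tenth of regions
  fail the 1000-unit filter, a realistic attrition rate for lncRNA-scale expression; channels split by
  allele dosage plus Gaussian fraction noise (sd 0.05), clipped at 0; the x
  channel is then multiplied by the smooth gain 1 + 0.3·log10(t)/4 — exactly
  the distortion class the normalization models, so the module is exercised
  end to end.
- Cis effects: half the regions get a causal SNP among their region SNPs;
  het carriers express haplotype 1 at fraction 0.6 (oriented by the phase of
  the causal SNP), giving a true window ASE of ±0.1 — twice the slope
  threshold. 20% of effect regions are co-expressed with their gene
  (multiplier 1 + 0.3·(dosage−1) on both transcripts' cDNA totals), split
  ≈ 21:19:12 between co-regulated (gene ASE driven by the same SNP),
  lnc-only, and non-evaluable-gene pairs.
- QC decoys: per-call missingness 10⁻³, 1% low-call-rate SNPs, 0.5%
  HWE-violating SNPs (forced all-het), one low-call-rate sample, one
  contaminated sample with 50% cDNA call rate (normal samples 15%).
- Peaks: background density 25/Mb (H3K4me1) and 8/Mb (H3K27ac), widths
  ~N(1500, 300) bp; each true cis-rSNP gains a covering peak with
  probability (odds−1)×coverage (odds 3 by default, odds 1 reproduces the
  null exactly); every peak is emitted per replicate with probability 0.85,
  jittered ±100 bp, and 10% of emissions get a weak p-value failing the
  consensus threshold.
- Catalog: 15% of causal SNPs become members (immune trait with probability
  0.5) plus 300 decoys, half null panel SNPs and half foreign rsIDs (immune
  probability 0.15).

Identical config + seed reproduces byte-identical files. What the generator
does **not** emulate: cross-hybridization, batch and plate effects,
population structure, genotyping-caller error correlated with intensity, and
isoform structure; passing tests therefore demonstrate the statistical
machinery under the declared noise model, not robustness to array artifacts
beyond it.

## Problem sizes and numerical conventions

The default bundle (300 regions, ~6000 SNPs, 188 samples) runs the full
pipeline in well under a minute on one CPU; the calibration suites use 10⁴
null regressions and 200 effect regions, chosen to give stable rates at
interactive runtimes. Tolerances used in tests mirror the contracts above
(2% gain recovery, 0.01 decile restoration, binomial 99% interval for the
type-I rate, ±0.02 slope recovery, ≥ 90% detection). Ties and degenerate
inputs are resolved as stated per stage; all interval arithmetic is 0-based
half-open internally with conversion only at I/O boundaries (panel positions
1-based). Allele labels A/B are abstract: the package never
reverse-complements or re-orients strands.

## Known limitations

Strand-specific and isoform-level expression are out of reach of SNP-array
ASE; trans effects are invisible by design; the normalization is a
reconstruction validated against its contract rather than the original
equations; co-expression uses raw intensities, so array-scale differences
between regions enter the expression covariate only through the genotype
grouping, not as a confounder correction.
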