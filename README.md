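# aselnc

Mapping *cis*-regulatory SNPs (cis-rSNPs) for long non-coding RNA regions by
allele-specific expression (ASE) analysis of two-channel SNP-array data, with
a synthetic-data generator providing known ground truth for every stage.

## Who this is for and what it does

Regulatory variants that act in *cis* shift the balance between the two
alleles of a transcript inside the same cell, so comparing the allele ratio
measured in RNA (cDNA) with the ratio in genomic DNA (gDNA) of the same
sample cancels trans-acting and environmental effects and gives a sensitive
readout for *cis* regulation — particularly valuable for lncRNAs, which are
expressed too low for conventional eQTL arrays. This package implements that
analysis for paired gDNA/cDNA two-channel genotyping intensities:

1. **Normalization** — per channel, a quadratic in log10 of the summed signal
   through binned medians removes the intensity-dependent dye bias from
   allele fractions.
2. **QC** — genotype call-rate filters (SNPs ≥ 99%, samples ≥ 98%),
   Hardy–Weinberg equilibrium (1-df χ², removal at p < 10⁻⁶), and removal of
   samples whose cDNA call rate exceeds 40% (DNA contamination).
3. **Window ASE** — per heterozygous SNP and sample,
   `ASE = f_cDNA − f_gDNA` with both adjusted allele fractions oriented to
   haplotype 1; per region ("ASE window"), the mean over that sample's het
   SNPs. Windows need ≥ 3 informative SNPs and a mean summed cDNA signal
   ≥ 1000 fluorescence units.
4. **Association** — for every SNP within ±250 kb of a window, samples are
   coded by phased genotype (hom → 0, A|B → +1, B|A → −1) and window ASE is
   regressed on the code; a cis-rSNP requires p < 10⁻⁶, |slope| ≥ 0.05
   (≈ 20% allelic expression difference, since percent difference =
   400·slope) and ≥ 4 samples per allele combination.
5. **Enhancer enrichment** — replicate ChIP-seq peak sets (H3K27ac active,
   H3K4me1 poised) reconciled into consensus peaks (p ≤ 10⁻⁵ in ≥ 2 of 4
   replicates with > 50% overlap); fold enrichment of cis-rSNPs in peaks vs
   non-significant SNPs (p > 0.5) with a two-sided Fisher's exact test.
6. **Co-expression** — expression of a regulated lncRNA's nearest
   protein-coding gene regressed on the three genotype groups of the top
   cis-rSNP (AA / AB,BA / BB coded 0/1/2), Benjamini–Hochberg FDR at 10%,
   then a three-way classification: `co_regulated` (gene ASE also driven by
   the same SNP), `lnc_only`, or `unknown` (gene not evaluable).
7. **GWAS overlap** — intersection of cis-rSNPs with a GWAS-catalog table,
   directly or via LD proxies (haplotype r² ≥ 0.8), with enhancer context and
   an immune-trait over-representation test.

The `aselnc.simulate` module generates complete input bundles — panel,
phased haplotypes with block LD, genotype calls, gDNA/cDNA channel
intensities with dye bias, replicate peak sets, a GWAS-catalog-like table —
plus a truth table, so the whole pipeline is testable without any external
data.

## Worked example

```python
from aselnc import SimulationConfig, simulate_bundle, write_bundle, run_pipeline

data = simulate_bundle(SimulationConfig(seed=3, n_regions=60))
write_bundle(data, "bundle")
manifest = run_pipeline("bundle", "results")
print(manifest.counts)
```

prints (seed 3):

```
{'snps_retained': 1155, 'samples_retained': 186, 'regions_total': 60,
 'regions_informative': 60, 'regions_expressed': 57, 'snps_tested': 1068,
 'snps_significant': 36, 'regions_significant': 28, 'coexpressed_pairs': 7,
 'gwas_overlaps': 1}
```

Reading the funnel: of 60 simulated regions, all have ≥ 3 informative SNPs,
57 pass the 1000-unit expression filter, and 28 end up with at least one
significant cis-rSNP — against 31 regions carrying a planted effect, i.e.
28/31 recovered with no false-positive region. The strongest hit,

```
region_id   snp_id   distance_bp  slope     p_value      n_ab n_ba n_hom
LNC0060     rs001184           0  0.100850  1.92e-66       50   46    68
```

recovers the planted effect size: a heterozygote cDNA fraction of 0.6 means
a window ASE of ±0.1 depending on phase, and the fitted slope is 0.1008 —
a 40% expression difference between alleles (400 × slope).

Equivalent shell interface: `aselnc simulate --seed 3 --n-regions 60 --out
bundle && aselnc run --bundle bundle --out results`. The `examples/`
directory has one short script per capability (simulation, normalization,
full pipeline, enrichment + GWAS overlap).

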