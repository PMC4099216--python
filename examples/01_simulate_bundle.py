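"""Generate a synthetic input bundle with known ground truth.

The generator emulates the study design end to end: 188 samples typed in
paired gDNA/cDNA templates on a two-channel array, lncRNA regions with ~5
on-array SNPs plus candidate SNPs within +/-250 kb, block-LD genotypes in
Hardy-Weinberg proportions, an intensity-dependent dye bias, and cis effects
that shift heterozygote cDNA allele fractions to 0.6 (a window ASE of 0.1).
"""

from pathlib import Path

from aselnc import SimulationConfig, simulate_bundle, write_bundle

cfg = SimulationConfig(seed=42, n_regions=30)
data = simulate_bundle(cfg)
out = Path("example_bundle")
write_bundle(data, out)

truth = data.truth
n_effect = (truth["true_cis_rsnp_id"] != "NA").sum()
print(f"bundle written to {out}/")
print(f"regions: {len(data.regions)}, SNPs on panel: {len(data.panel)}, "
      f"samples: {data.genotypes.shape[0]}")
print(f"regions with a true cis-rSNP: {n_effect} "
      f"(het cDNA fraction {cfg.het_cdna_fraction_under_effect} -> "
      f"expected window ASE {cfg.het_cdna_fraction_under_effect - 0.5:.2f})")
print(truth.head(8).to_string(index=False))
# Each row records a region's planted truth: its causal SNP (or NA), the
# heterozygote cDNA fraction it induces, whether the neighbouring gene is
# co-expressed, and whether the causal SNP was placed in the GWAS catalog.
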