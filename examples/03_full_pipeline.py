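"""Run the complete cis-rSNP mapping pipeline on a synthetic bundle.

Stages: QC (call rate, Hardy-Weinberg, cDNA contamination) -> normalization ->
window ASE -> association of window ASE with phased candidate-SNP codes ->
enhancer-peak enrichment -> co-expression classification -> GWAS-catalog
overlap.  The truth table lets us score the run.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aselnc import PipelineConfig, SimulationConfig, run_pipeline, simulate_bundle, write_bundle

tmp = Path(tempfile.mkdtemp(prefix="aselnc_example_"))
data = simulate_bundle(SimulationConfig(seed=3, n_regions=60))
write_bundle(data, tmp / "bundle")

manifest = run_pipeline(tmp / "bundle", tmp / "results", PipelineConfig())
print("funnel:", {k: v for k, v in manifest.counts.items()})

assoc = pd.read_csv(tmp / "results" / "associations.tsv", sep="\t")
sig = assoc[assoc["significant"]]
truth = data.truth
eff = truth[truth["true_cis_rsnp_id"] != "NA"]
detected = sum(
    ((sig["region_id"] == r.region_id) & (sig["snp_id"] == r.true_cis_rsnp_id)).any()
    for r in eff.itertuples()
)
print(f"\nplanted cis-rSNPs: {len(eff)}; recovered as significant: {detected}")
print(f"strongest association:\n{sig.nsmallest(3, 'p_value').to_string(index=False)}")

coexpr = pd.read_csv(tmp / "results" / "coexpression.tsv", sep="\t")
print("\nco-expression categories of FDR-passing pairs:")
print(coexpr.loc[coexpr["fdr_pass"], "category"].value_counts().to_string())
# A slope of ~0.1 at a true cis-rSNP corresponds to a ~40% expression
# difference between alleles (percent difference = 400 x slope); the
# co-expression categories separate SNPs driving both transcripts
# (co_regulated) from lncRNA-specific regulation (lnc_only).
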