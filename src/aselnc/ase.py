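"""Per-SNP and window-level allele-specific expression with phased signs.

The ASE level of a heterozygous SNP in one sample is the difference between
its normalized cDNA and gDNA allele fractions, both oriented to the allele
carried on haplotype 1:

    ASE = f_cDNA(hap1 allele) - f_gDNA(hap1 allele)

The gDNA fraction, where the two alleles are present 1:1, is the sample's own
quantification standard, absorbing probe- and sequence-context bias.  A
region's ("ASE window") level per sample is the mean over that sample's
heterozygous SNPs; regions need >= 3 informative SNP positions and a mean raw
cDNA signal >= 1000 fluorescence units to enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RegionRecord, SnpRecord

HET_CALLS = ("AB", "BA")

# exclusion reason codes for windows
REASON_NO_SNPS = "no_snps"
REASON_TOO_FEW_INFORMATIVE = "lt3_informative"
REASON_LOW_EXPRESSION = "below_expression_threshold"
REASON_OK = "ok"


@dataclass
class AseWindow:
    region: RegionRecord
    informative_snps: list[SnpRecord]
    ase_by_sample: pd.Series  # signed window ASE; NaN where no het SNPs
    mean_expression: float
    passed: bool
    reason: str = REASON_OK


def snp_ase(cdna_fraction: float, gdna_fraction: float) -> float:
    """Signed per-SNP ASE level: cDNA fraction minus gDNA fraction (phase-oriented)."""
    return cdna_fraction - gdna_fraction


def orient_fraction(a_fraction, hap1_is_a):
    """Orient an allele-A fraction to haplotype 1: f if hap1 carries A, else 1-f."""
    a_fraction = np.asarray(a_fraction, dtype=float)
    hap1_is_a = np.asarray(hap1_is_a, dtype=bool)
    return np.where(hap1_is_a, a_fraction, 1.0 - a_fraction)


def expression_level(cdna_x: pd.DataFrame, cdna_y: pd.DataFrame) -> float:
    """Mean over SNPs and samples of the summed raw cDNA channel signals."""
    total = cdna_x.to_numpy(dtype=float) + cdna_y.to_numpy(dtype=float)
    if total.size == 0 or np.all(np.isnan(total)):
        return float("nan")
    return float(np.nanmean(total))


def expression_filter(mean_expression: float, thresh: float = 1000.0) -> bool:
    """Inclusive threshold on the window's mean summed cDNA signal."""
    return bool(mean_expression >= thresh)


def region_snps(region: RegionRecord, panel: list[SnpRecord]) -> list[SnpRecord]:
    """Panel SNPs whose 1-based position falls inside the (0-based half-open) region."""
    return [s for s in panel if s.chrom == region.chrom and region.contains_pos(s.pos)]


def _hap1_is_a(haplotypes: pd.DataFrame, snp_id: str) -> pd.Series:
    """Boolean per sample: does haplotype 1 carry allele A at this SNP (phased 'A|B')."""
    col = haplotypes[snp_id]
    return col.str.split("|", expand=True)[0] == "A"


def window_ase(
    region: RegionRecord,
    panel: list[SnpRecord],
    genotypes: pd.DataFrame,
    haplotypes: pd.DataFrame,
    gdna_frac: pd.DataFrame,
    cdna_frac: pd.DataFrame,
    cdna_x: pd.DataFrame,
    cdna_y: pd.DataFrame,
    min_informative: int = 3,
    expression_thresh: float = 1000.0,
) -> AseWindow:
    """Build one region's ASE window from adjusted fractions and phased calls.

    An informative SNP is heterozygous in gDNA in at least one retained sample
    and has non-missing cDNA intensity there.  Per sample, the window ASE is
    the mean of phase-oriented per-SNP ASE over the sample's own het SNPs.
    """
    snps = region_snps(region, panel)
    samples = genotypes.index
    empty = pd.Series(np.nan, index=samples, dtype=float)
    if not snps:
        return AseWindow(region, [], empty, float("nan"), False, REASON_NO_SNPS)

    snp_ids = [s.snp_id for s in snps]
    present = [sid for sid in snp_ids if sid in genotypes.columns]
    if not present:
        return AseWindow(region, [], empty, float("nan"), False, REASON_NO_SNPS)
    snps = [s for s in snps if s.snp_id in present]
    snp_ids = present

    mean_expr = expression_level(cdna_x[snp_ids], cdna_y[snp_ids])

    contrib = pd.DataFrame(np.nan, index=samples, columns=snp_ids, dtype=float)
    informative: list[SnpRecord] = []
    for snp in snps:
        sid = snp.snp_id
        het = genotypes[sid].isin(HET_CALLS)
        has_cdna = cdna_frac[sid].notna() & gdna_frac[sid].notna()
        usable = (het & has_cdna).to_numpy()
        if not usable.any():
            continue
        informative.append(snp)
        hap1_a = _hap1_is_a(haplotypes, sid).to_numpy()
        c_or = orient_fraction(cdna_frac[sid].to_numpy(), hap1_a)
        g_or = orient_fraction(gdna_frac[sid].to_numpy(), hap1_a)
        ase = c_or - g_or
        contrib.loc[usable, sid] = ase[usable]

    ase_by_sample = contrib.mean(axis=1, skipna=True)
    ase_by_sample[contrib.notna().sum(axis=1) == 0] = np.nan

    if len(informative) < min_informative:
        return AseWindow(region, informative, ase_by_sample, mean_expr, False,
                         REASON_TOO_FEW_INFORMATIVE)
    if not expression_filter(mean_expr, expression_thresh):
        return AseWindow(region, informative, ase_by_sample, mean_expr, False,
                         REASON_LOW_EXPRESSION)
    return AseWindow(region, informative, ase_by_sample, mean_expr, True, REASON_OK)


def build_windows(
    regions: list[RegionRecord],
    panel: list[SnpRecord],
    genotypes: pd.DataFrame,
    haplotypes: pd.DataFrame,
    gdna_frac: pd.DataFrame,
    cdna_frac: pd.DataFrame,
    cdna_x: pd.DataFrame,
    cdna_y: pd.DataFrame,
    min_informative: int = 3,
    expression_thresh: float = 1000.0,
) -> list[AseWindow]:
    return [
        window_ase(r, panel, genotypes, haplotypes, gdna_frac, cdna_frac,
                   cdna_x, cdna_y, min_informative, expression_thresh)
        for r in regions
    ]


def windows_to_frame(windows: list[AseWindow]) -> pd.DataFrame:
    """ase_windows table: region metadata plus one ASE column per sample."""
    rows = []
    for w in windows:
        row = {
            "region_id": w.region.region_id,
            "n_informative_snps": len(w.informative_snps),
            "mean_expression": w.mean_expression,
            "passed_filters": w.passed,
            "reason": w.reason,
        }
        row.update({f"ase_{s}": v for s, v in w.ase_by_sample.items()})
        rows.append(row)
    return pd.DataFrame(rows)
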