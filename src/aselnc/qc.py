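"""SNP- and sample-level quality-control filters applied before ASE.

Filters: genotype call rate (>=99% per SNP, then >=98% per sample on retained
SNPs), Hardy-Weinberg equilibrium (1-df chi-square, removal at p < 1e-6), and
a DNA-contamination flag for samples whose cDNA call rate exceeds 40% —
genomic DNA in an RNA template makes heterozygous SNPs callable that pure
cDNA, with its allelic imbalance and lower complexity, would drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QcReport:
    snps_removed_callrate: int = 0
    snps_removed_hwe: int = 0
    samples_removed_callrate: int = 0
    samples_removed_contamination: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"filter": ["snp_call_rate", "snp_hwe", "sample_call_rate", "sample_contamination"],
             "removed": [self.snps_removed_callrate, self.snps_removed_hwe,
                         self.samples_removed_callrate, self.samples_removed_contamination]}
        )


def call_rate_filter(
    genotypes: pd.DataFrame,
    snp_thresh: float = 0.99,
    sample_thresh: float = 0.98,
) -> tuple[pd.Index, pd.Index]:
    """Retained (snp_ids, sample_ids); SNP filter first, then samples on retained SNPs.

    A SNP/sample is retained iff its non-missing fraction is >= the threshold
    (inclusive boundaries).
    """
    if genotypes.size == 0:
        raise ValueError("genotype matrix is empty")
    called = genotypes.notna()
    snp_rate = called.mean(axis=0)
    keep_snps = snp_rate.index[snp_rate >= snp_thresh]
    sample_rate = called.loc[:, keep_snps].mean(axis=1) if len(keep_snps) else pd.Series(
        0.0, index=genotypes.index
    )
    keep_samples = sample_rate.index[sample_rate >= sample_thresh]
    return keep_snps, keep_samples


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Allele frequencies are estimated from the same counts.  A monomorphic SNP
    returns (0, 1) by convention.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def hwe_filter(genotypes: pd.DataFrame, p_thresh: float = 1e-6) -> pd.Index:
    """SNP ids flagged for removal (HWE p < p_thresh) on call-string genotypes."""
    flagged = []
    for snp_id in genotypes.columns:
        col = genotypes[snp_id].dropna()
        n_aa = int((col == "AA").sum())
        n_ab = int(col.isin(["AB", "BA"]).sum())
        n_bb = int((col == "BB").sum())
        if n_aa + n_ab + n_bb == 0:
            continue
        _, p = hwe_chisq(n_aa, n_ab, n_bb)
        if p < p_thresh:
            flagged.append(snp_id)
    return pd.Index(flagged)


def contamination_filter(cdna_calls: pd.DataFrame, thresh: float = 0.40) -> pd.Index:
    """Samples whose cDNA call rate is strictly greater than ``thresh``."""
    rate = cdna_calls.notna().mean(axis=1)
    return rate.index[rate > thresh]


def run_qc(
    genotypes: pd.DataFrame,
    cdna_calls: pd.DataFrame | None = None,
    snp_thresh: float = 0.99,
    sample_thresh: float = 0.98,
    hwe_p: float = 1e-6,
    contamination_thresh: float = 0.40,
) -> tuple[pd.Index, pd.Index, QcReport]:
    """Full QC chain; returns retained SNP ids, sample ids and a report.

    Order: call-rate filters, then HWE on the call-rate-retained matrix, then
    the cDNA contamination flag.  The chain is idempotent: rerunning it on the
    filtered matrix removes nothing further.
    """
    keep_snps, keep_samples = call_rate_filter(genotypes, snp_thresh, sample_thresh)
    report = QcReport(
        snps_removed_callrate=genotypes.shape[1] - len(keep_snps),
        samples_removed_callrate=genotypes.shape[0] - len(keep_samples),
    )
    sub = genotypes.loc[keep_samples, keep_snps]
    bad_hwe = hwe_filter(sub, hwe_p)
    report.snps_removed_hwe = len(bad_hwe)
    keep_snps = keep_snps.difference(bad_hwe, sort=False)
    if cdna_calls is not None:
        contaminated = contamination_filter(
            cdna_calls.reindex(index=keep_samples), contamination_thresh
        )
        report.samples_removed_contamination = len(contaminated)
        keep_samples = keep_samples.difference(contaminated, sort=False)
    return keep_snps, keep_samples, report
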