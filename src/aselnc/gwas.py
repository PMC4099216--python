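"""Overlap of cis-rSNPs with a GWAS-catalog table and immune-trait enrichment.

A catalog SNP overlaps a region's cis-regulation either directly (it is itself
a significant cis-rSNP for the region) or through an LD proxy (some
significant cis-rSNP of the region has r^2 >= 0.8 with it on the provided
haplotypes).  Each overlap is annotated with its enhancer context (inside an
H3K4me1 or H3K27ac consensus peak, within the 2.5 kb flanks, or none), and
over-representation of immune-related traits among overlapped catalog SNPs is
tested with a two-sided Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import ld_r2
from .enrichment import IntervalSet
from .io import GwasRecord, SnpRecord

CONTEXT_NONE = "none"
CONTEXT_FLANK = "flank_2.5kb"


@dataclass
class OverlapRecord:
    region_id: str
    cis_rsnp_id: str
    catalog_snp_id: str
    ld_r2: float
    trait: str
    in_peak: str = CONTEXT_NONE
    ase_p: float = float("nan")
    slope: float = float("nan")
    distance_bp: int = -1


def haplotype_01(haplotypes: pd.DataFrame, snp_id: str) -> np.ndarray:
    """Stack the phased calls of one SNP into a 2n binary vector (1 = allele B)."""
    parts = haplotypes[snp_id].str.split("|", expand=True)
    h = pd.concat([parts[0], parts[1]]).to_numpy()
    return (h == "B").astype(float)


def enhancer_context(
    chrom: str,
    pos_1based: int,
    peaks_by_mark: dict[str, IntervalSet],
    flanks_by_mark: dict[str, IntervalSet],
) -> str:
    """Annotation priority: in-peak (H3K4me1 before H3K27ac), then flank, then none."""
    for mark in ("H3K4me1", "H3K27ac"):
        ivs = peaks_by_mark.get(mark)
        if ivs is not None and ivs.contains_positions([chrom], [pos_1based])[0]:
            return f"in_{mark}"
    for mark in ("H3K4me1", "H3K27ac"):
        ivs = flanks_by_mark.get(mark)
        if ivs is not None and ivs.contains_positions([chrom], [pos_1based])[0]:
            return CONTEXT_FLANK
    return CONTEXT_NONE


def overlap_catalog(
    associations: pd.DataFrame,
    catalog: list[GwasRecord],
    panel: list[SnpRecord],
    haplotypes: pd.DataFrame,
    r2_thresh: float = 0.8,
    peaks_by_mark: dict[str, IntervalSet] | None = None,
    flanks_by_mark: dict[str, IntervalSet] | None = None,
) -> list[OverlapRecord]:
    """One record per (region, catalog SNP, trait) with a direct or proxy link.

    Direct matches carry ld_r2 = 1.0.  Catalog SNPs absent from the haplotype
    panel are skipped for the proxy search (still eligible for direct match).
    """
    sig = associations[associations["significant"]]
    if sig.empty:
        return []
    panel_by_id = {s.snp_id: s for s in panel}
    sig_by_region: dict[str, list[str]] = {}
    assoc_info: dict[tuple[str, str], tuple[float, float, int]] = {}
    for row in sig.itertuples(index=False):
        sig_by_region.setdefault(row.region_id, []).append(row.snp_id)
        assoc_info[(row.region_id, row.snp_id)] = (
            float(row.p_value), float(row.slope), int(row.distance_bp))

    hap_cache: dict[str, np.ndarray] = {}

    def hap(sid: str) -> np.ndarray:
        if sid not in hap_cache:
            hap_cache[sid] = haplotype_01(haplotypes, sid)
        return hap_cache[sid]

    records: list[OverlapRecord] = []
    for region_id, snp_ids in sorted(sig_by_region.items()):
        snp_set = set(snp_ids)
        for rec in catalog:
            best: tuple[float, str] | None = None
            if rec.snp_id in snp_set:
                best = (1.0, rec.snp_id)
            elif rec.snp_id in panel_by_id and rec.snp_id in haplotypes.columns:
                cat_hap = hap(rec.snp_id)
                for sid in snp_ids:
                    if sid not in haplotypes.columns:
                        continue
                    r2 = ld_r2(hap(sid), cat_hap)
                    if np.isfinite(r2) and r2 >= r2_thresh:
                        if best is None or r2 > best[0]:
                            best = (r2, sid)
            if best is None:
                continue
            r2, cis_id = best
            context = CONTEXT_NONE
            if peaks_by_mark is not None and cis_id in panel_by_id:
                snp = panel_by_id[cis_id]
                context = enhancer_context(
                    snp.chrom, snp.pos, peaks_by_mark, flanks_by_mark or {}
                )
            ase_p, slope, dist = assoc_info[(region_id, cis_id)]
            records.append(
                OverlapRecord(region_id, cis_id, rec.snp_id, float(r2), rec.trait,
                              context, ase_p, slope, dist)
            )
    return records


def trait_enrichment(
    overlaps: list[OverlapRecord], catalog: list[GwasRecord]
) -> float:
    """Two-sided Fisher p for immune-trait over-representation among overlapped SNPs.

    The 2x2 table is over unique catalog SNPs: overlapped yes/no x immune
    yes/no (a SNP is immune if any of its catalog traits is immune-related).
    Returns NaN if the catalog is all-immune or immune-free; 1.0 with no
    overlaps.
    """
    immune_by_snp: dict[str, bool] = {}
    for rec in catalog:
        immune_by_snp[rec.snp_id] = immune_by_snp.get(rec.snp_id, False) or rec.immune_related
    n_imm = sum(immune_by_snp.values())
    if n_imm == 0 or n_imm == len(immune_by_snp):
        return float("nan")
    overlapped = {o.catalog_snp_id for o in overlaps}
    if not overlapped:
        return 1.0
    a = sum(1 for s in overlapped if immune_by_snp.get(s, False))
    b = len(overlapped) - a
    c = n_imm - a
    d = (len(immune_by_snp) - n_imm) - b
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def overlaps_to_frame(overlaps: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(o) for o in overlaps],
        columns=["region_id", "cis_rsnp_id", "catalog_snp_id", "ld_r2", "trait",
                 "in_peak", "ase_p", "slope", "distance_bp"],
    )
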