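"""Synthetic input bundles with known ground truth for every pipeline stage.

The generator emulates the measured study design: 188 monocyte samples typed
on a two-channel SNP array in paired gDNA/cDNA templates, lncRNA regions with
a handful of on-array SNPs plus candidate SNPs within +/-250 kb, biallelic
genotypes in Hardy-Weinberg proportions with block LD, lognormal per-SNP
intensities (median ~3200 fluorescence units, matching the expressed-lncRNA
scale), an intensity-dependent multiplicative dye bias on one channel, cis
effects that shift the heterozygous cDNA allele fraction away from 0.5 in the
direction set by the phased haplotype, replicate enhancer peak sets enriched
near true cis-rSNPs, and a GWAS-catalog-like table holding a subset of true
cis-rSNPs plus decoys.  Identical config + seed reproduces byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from . import io as aio
from .io import GwasRecord, PeakRecord, RegionRecord, SnpRecord

IMMUNE_TRAITS = [
    "Rheumatoid arthritis", "Multiple sclerosis", "Celiac disease",
    "Graves disease", "Ankylosing spondylitis", "Eosinophilic esophagitis",
]
OTHER_TRAITS = [
    "Height", "Colorectal cancer", "Bone mineral density", "Longevity",
    "Chronic kidney disease", "Endometriosis", "Cognitive test performance",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated study conditions."""

    seed: int
    n_samples: int = 188
    n_regions: int = 300
    snps_per_region: int = 5
    flank_snps: int = 10
    region_len: int = 20_000
    region_spacing: int = 1_400_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_rho: float = 0.6
    cis_effect_fraction: float = 0.5
    het_cdna_fraction_under_effect: float = 0.6
    intensity_log10_mean: float = 3.5
    intensity_log10_sd: float = 0.25
    region_expr_log10_sd: float = 0.35
    snp_intensity_log10_sd: float = 0.10
    sample_intensity_log10_sd: float = 0.10
    dye_bias_coeffs: tuple[float, float] = (0.3, 4.0)
    noise_sd: float = 0.05
    call_missing_rate: float = 0.001
    bad_snp_fraction: float = 0.01
    bad_snp_missing_rate: float = 0.05
    hwe_violation_fraction: float = 0.005
    n_bad_samples: int = 1
    bad_sample_missing_rate: float = 0.05
    base_cdna_call_rate: float = 0.15
    n_contaminated: int = 1
    contaminated_cdna_call_rate: float = 0.50
    coexpressed_fraction: float = 0.20
    coexpr_effect: float = 0.30
    category_probs: tuple[float, float, float] = (21 / 52, 19 / 52, 12 / 52)
    gene_distance: int = 50_000
    gene_distance_far: int = 300_000
    peak_enrichment_odds: float = 3.0
    n_peak_replicates: int = 4
    peak_width_mean: float = 1500.0
    peak_width_sd: float = 300.0
    peak_density_per_mb: dict = field(
        default_factory=lambda: {"H3K4me1": 25.0, "H3K27ac": 8.0}
    )
    peak_rep_inclusion: float = 0.85
    peak_jitter_sd: float = 100.0
    peak_weak_fraction: float = 0.10
    catalog_fraction: float = 0.15
    n_catalog_decoys: int = 300
    member_immune_prob: float = 0.5
    decoy_immune_prob: float = 0.15
    phase_switch_error_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("cis_effect_fraction", "het_cdna_fraction_under_effect",
                     "coexpressed_fraction", "peak_rep_inclusion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")


@dataclass
class SimulatedData:
    config: SimulationConfig
    panel: list[SnpRecord]
    regions: list[RegionRecord]
    gene_regions: list[RegionRecord]
    haplotypes: pd.DataFrame  # phased "A|B" strings, samples x SNPs
    genotypes: pd.DataFrame  # gDNA calls "AA"/"AB"/"BB"/NA
    cdna_calls: pd.DataFrame
    gdna_x: pd.DataFrame
    gdna_y: pd.DataFrame
    cdna_x: pd.DataFrame
    cdna_y: pd.DataFrame
    peaks: dict[str, list[list[PeakRecord]]]  # mark -> replicate sets
    catalog: list[GwasRecord]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# layout


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Regions, gene regions, SNP panel and per-region SNP index blocks."""
    panel: list[SnpRecord] = []
    regions: list[RegionRecord] = []
    gene_regions: list[RegionRecord] = []
    blocks: list[list[int]] = []
    meta_rows = []
    snp_counter = 0

    def add_snp(chrom: str, pos: int) -> int:
        nonlocal snp_counter
        snp_counter += 1
        panel.append(SnpRecord(f"rs{snp_counter:06d}", chrom, pos, "A", "B"))
        return snp_counter - 1

    for i in range(cfg.n_regions):
        chrom = "chr1"
        start = 1_000_000 + i * cfg.region_spacing  # 0-based
        end = start + cfg.region_len
        rid = f"LNC{i + 1:04d}"
        regions.append(RegionRecord(rid, chrom, start, end, "intergenic"))

        coexpressed = rng.random() < cfg.coexpressed_fraction
        category = None
        if coexpressed:
            category = ["co_regulated", "lnc_only", "unknown"][
                int(rng.choice(3, p=np.asarray(cfg.category_probs) / sum(cfg.category_probs)))
            ]
        gdist = cfg.gene_distance_far if category == "unknown" else cfg.gene_distance
        gene_start = end + gdist
        gid = f"GENE{i + 1:04d}"
        gene_regions.append(
            RegionRecord(gid, chrom, gene_start, gene_start + cfg.region_len,
                         "protein_coding")
        )

        block: list[int] = []
        in_region_idx: list[int] = []
        # SNPs inside the lncRNA region, evenly spaced (1-based positions)
        for j in range(cfg.snps_per_region):
            pos = start + 1 + int((j + 0.5) * cfg.region_len / cfg.snps_per_region)
            in_region_idx.append(add_snp(chrom, pos))
        # flanking candidate SNPs in the +/-250 kb window, kept out of the
        # transcribed intervals so their cDNA carries no window ASE signal
        flank_pos = []
        while len(flank_pos) < cfg.flank_snps:
            p = int(rng.uniform(start - 250_000 + 1, end + 250_000))
            in_lnc = start < p <= end
            in_gene = gene_start < p <= gene_start + cfg.region_len
            if not in_lnc and not in_gene:
                flank_pos.append(p)
        flank_idx = [add_snp(chrom, p) for p in sorted(flank_pos)]
        # SNPs inside the protein-coding gene region
        gene_idx = [
            add_snp(chrom, gene_start + 1 + int((j + 0.5) * cfg.region_len / cfg.snps_per_region))
            for j in range(cfg.snps_per_region)
        ]
        block = sorted(in_region_idx + flank_idx + gene_idx, key=lambda k: panel[k].pos)
        blocks.append(block)
        meta_rows.append(
            {"region_id": rid, "gene_id": gid, "in_region_idx": in_region_idx,
             "gene_idx": gene_idx, "coexpressed": coexpressed, "category": category}
        )
    return panel, regions, gene_regions, blocks, meta_rows


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    n_samples: int,
    blocks: list[list[int]],
    n_snps: int,
    maf_range: tuple[float, float],
    ld_block_rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(2*n_samples, n_snps) haplotype matrix of allele-B indicators.

    Allele-B frequencies are drawn from maf_range and assigned to the minor or
    major allele with equal probability (label symmetry); within a block,
    adjacent SNPs share a latent AR(ld_block_rho) Gaussian, thresholded at the
    allele-frequency quantile, so genotypes obey Hardy-Weinberg by random
    haplotype pairing while carrying LD.
    """
    n_hap = 2 * n_samples
    maf = rng.uniform(*maf_range, size=n_snps)
    # label symmetry: with prob 0.5 allele B is the major allele, implemented
    # by complementing the minor-allele indicator (preserves |r| within blocks)
    flip = rng.random(n_snps) < 0.5
    p_b = np.where(flip, 1.0 - maf, maf)
    haps = np.zeros((n_hap, n_snps), dtype=np.int8)
    for block in blocks:
        m = len(block)
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        innov = rng.standard_normal((n_hap, m - 1)) if m > 1 else None
        for j in range(1, m):
            z[:, j] = ld_block_rho * z[:, j - 1] + np.sqrt(1 - ld_block_rho ** 2) * innov[:, j - 1]
        thresh = _norm.ppf(maf[block])
        minor = (z < thresh[None, :]).astype(np.int8)
        haps[:, block] = np.where(flip[block][None, :], 1 - minor, minor)
    return haps, p_b


# ---------------------------------------------------------------------------
# intensities


def _dye_bias(total: np.ndarray, coeffs: tuple[float, float]) -> np.ndarray:
    c0, c1 = coeffs
    with np.errstate(divide="ignore", invalid="ignore"):
        lt = np.log10(np.maximum(total, 1e-12))
    return 1.0 + c0 * lt / c1


def simulate_intensities(
    frac_a: np.ndarray,
    totals: np.ndarray,
    noise_sd: float,
    dye_bias_coeffs: tuple[float, float] | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-entry totals into two noisy channels, then distort channel x.

    frac_a is the true allele-A signal fraction per sample x SNP; the dye bias
    multiplies the x channel by 1 + c0*log10(total)/c1.  Negative values are
    clipped to 0.
    """
    eps_x = rng.normal(0.0, noise_sd, size=frac_a.shape)
    eps_y = rng.normal(0.0, noise_sd, size=frac_a.shape)
    x = np.clip(totals * (frac_a + eps_x), 0.0, None)
    y = np.clip(totals * (1.0 - frac_a + eps_y), 0.0, None)
    if dye_bias_coeffs is not None:
        x = x * _dye_bias(x + y, dye_bias_coeffs)
    return x, y


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(
    truth_positions: list[tuple[str, int]],
    span: tuple[str, int, int],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[list[PeakRecord]]]:
    """Replicate peak sets per mark, enriched near true cis-rSNP positions.

    Background peaks are uniform over the span; each true cis-rSNP gains an
    extra covering peak with probability (odds-1) x background coverage, so
    odds = 1 reproduces the null.  Every placed peak is emitted in each
    replicate with probability peak_rep_inclusion, with jittered boundaries
    and a MACS-style p-value (a fraction of replicate emissions are weak and
    fail the 1e-5 consensus threshold).
    """
    chrom, lo, hi = span
    out: dict[str, list[list[PeakRecord]]] = {}
    for mark in sorted(cfg.peak_density_per_mb):
        density = cfg.peak_density_per_mb[mark]
        n_bg = int(density * (hi - lo) / 1e6)
        coverage = min(0.5, n_bg * cfg.peak_width_mean / max(hi - lo, 1))
        centers = list(rng.uniform(lo, hi, size=n_bg))
        p_extra = min(1.0, max(0.0, (cfg.peak_enrichment_odds - 1.0) * coverage))
        if p_extra > 0:
            for _, pos in truth_positions:
                if rng.random() < p_extra:
                    centers.append(pos - 1 + rng.normal(0.0, cfg.peak_width_mean / 10))
        widths = np.clip(
            rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, size=len(centers)),
            200.0, None,
        )
        replicates: list[list[PeakRecord]] = [[] for _ in range(cfg.n_peak_replicates)]
        for center, width in zip(centers, widths):
            for r in range(cfg.n_peak_replicates):
                if rng.random() > cfg.peak_rep_inclusion:
                    continue
                s = center - width / 2 + rng.normal(0.0, cfg.peak_jitter_sd)
                e = center + width / 2 + rng.normal(0.0, cfg.peak_jitter_sd)
                start, end = int(max(0, s)), int(max(0, e))
                if end <= start:
                    continue
                if rng.random() < cfg.peak_weak_fraction:
                    peak_p = 10.0 ** (-rng.uniform(2.0, 4.9))
                else:
                    peak_p = 10.0 ** (-rng.uniform(5.1, 12.0))
                replicates[r].append(
                    PeakRecord(chrom, start, end, mark, f"rep{r + 1}", peak_p)
                )
        out[mark] = [sorted(reps, key=lambda p: (p.start, p.end)) for reps in replicates]
    return out


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(cfg: SimulationConfig) -> SimulatedData:
    rng = np.random.default_rng(cfg.seed)
    panel, regions, gene_regions, blocks, meta = _build_layout(cfg, rng)
    n_snps = len(panel)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    snp_ids = [s.snp_id for s in panel]

    haps, _ = simulate_haplotypes(
        cfg.n_samples, blocks, n_snps, cfg.maf_range, cfg.ld_block_rho, rng
    )
    hap1 = haps[0::2, :]  # sample i -> haplotypes 2i, 2i+1
    hap2 = haps[1::2, :]
    if cfg.phase_switch_error_rate > 0:
        switch = rng.random(hap1.shape) < cfg.phase_switch_error_rate
        hap1, hap2 = np.where(switch, hap2, hap1), np.where(switch, hap1, hap2)
    dosage_b = hap1 + hap2  # 0/1/2 copies of allele B

    # truth assignment
    truth_rows = []
    effect_snp_idx: dict[str, int] = {}
    for i, m in enumerate(meta):
        is_effect = rng.random() < cfg.cis_effect_fraction
        eidx = int(rng.choice(m["in_region_idx"])) if is_effect else -1
        catalog_member = bool(is_effect and rng.random() < cfg.catalog_fraction)
        coexpressed = bool(m["coexpressed"] and is_effect)
        category = m["category"] if coexpressed else None
        truth_rows.append(
            {
                "region_id": m["region_id"],
                "true_cis_rsnp_id": panel[eidx].snp_id if is_effect else "NA",
                "het_cdna_fraction": cfg.het_cdna_fraction_under_effect if is_effect else 0.5,
                "coexpressed": coexpressed,
                "category": category if category else "NA",
                "gene_id": m["gene_id"],
                "catalog_member": catalog_member,
            }
        )
        if is_effect:
            effect_snp_idx[m["region_id"]] = eidx
    truth = pd.DataFrame(truth_rows)

    # HWE-violating SNPs (forced excess heterozygosity) and low-call-rate SNPs
    n_bad = int(round(cfg.bad_snp_fraction * n_snps))
    bad_snps = rng.choice(n_snps, size=n_bad, replace=False) if n_bad else np.array([], int)
    n_hwe = int(round(cfg.hwe_violation_fraction * n_snps))
    hwe_snps = rng.choice(n_snps, size=n_hwe, replace=False) if n_hwe else np.array([], int)
    for j in hwe_snps:  # every sample heterozygous: chi2 = n, p << 1e-6
        hap1[:, j] = 0
        hap2[:, j] = 1
        dosage_b[:, j] = 1

    # per-sample haplotype-1 expression share under the region's cis effect
    f_eff = cfg.het_cdna_fraction_under_effect
    phi = np.full((cfg.n_samples, len(regions)), 0.5)
    for i, m in enumerate(meta):
        rid = m["region_id"]
        if rid not in effect_snp_idx:
            continue
        e = effect_snp_idx[rid]
        het = dosage_b[:, e] == 1
        a_on_h1 = hap1[:, e] == 0
        phi[:, i] = np.where(het & a_on_h1, f_eff, np.where(het, 1.0 - f_eff, 0.5))

    # true cDNA allele-A fraction per sample x SNP
    frac_a_cdna = np.where(dosage_b == 0, 1.0, np.where(dosage_b == 2, 0.0, 0.5))
    region_of_snp = np.full(n_snps, -1)
    for i, block in enumerate(blocks):
        for j in block:
            region_of_snp[j] = i
    for i, m in enumerate(meta):
        cols = list(m["in_region_idx"])
        if m["category"] == "co_regulated" and truth.loc[i, "coexpressed"]:
            cols += list(m["gene_idx"])
        for j in cols:
            het = dosage_b[:, j] == 1
            a_on_h1 = hap1[:, j] == 0
            f = np.where(a_on_h1, phi[:, i], 1.0 - phi[:, i])
            frac_a_cdna[het, j] = f[het]

    # totals: gDNA flat lognormal; cDNA per-region expression scale with a
    # genotype-dependent multiplier for co-expressed pairs
    snp_mu_g = rng.normal(cfg.intensity_log10_mean, cfg.intensity_log10_sd, size=n_snps)
    totals_g = 10.0 ** (
        snp_mu_g[None, :]
        + rng.normal(0.0, cfg.sample_intensity_log10_sd, size=(cfg.n_samples, n_snps))
    )
    region_mu = rng.normal(cfg.intensity_log10_mean, cfg.region_expr_log10_sd,
                           size=len(regions))
    gene_mu = rng.normal(cfg.intensity_log10_mean, cfg.region_expr_log10_sd,
                         size=len(regions))
    snp_mu_c = np.empty(n_snps)
    for i, m in enumerate(meta):
        for j in m["in_region_idx"]:
            snp_mu_c[j] = region_mu[i]
        for j in m["gene_idx"]:
            snp_mu_c[j] = gene_mu[i]
    flank_mask = np.ones(n_snps, dtype=bool)
    for m in meta:
        flank_mask[m["in_region_idx"]] = False
        flank_mask[m["gene_idx"]] = False
    snp_mu_c[flank_mask] = rng.normal(
        cfg.intensity_log10_mean - 0.6, cfg.region_expr_log10_sd, size=int(flank_mask.sum())
    )
    snp_mu_c = snp_mu_c + rng.normal(0.0, cfg.snp_intensity_log10_sd, size=n_snps)
    totals_c = 10.0 ** (
        snp_mu_c[None, :]
        + rng.normal(0.0, cfg.sample_intensity_log10_sd, size=(cfg.n_samples, n_snps))
    )
    for i, m in enumerate(meta):
        rid = m["region_id"]
        if not truth.loc[i, "coexpressed"] or rid not in effect_snp_idx:
            continue
        dos = dosage_b[:, effect_snp_idx[rid]].astype(float)
        mult = 1.0 + cfg.coexpr_effect * (dos - 1.0)
        cols = list(m["in_region_idx"]) + list(m["gene_idx"])
        totals_c[:, cols] *= mult[:, None]

    frac_a_gdna = 1.0 - dosage_b / 2.0
    gx, gy = simulate_intensities(frac_a_gdna, totals_g, cfg.noise_sd,
                                  cfg.dye_bias_coeffs, rng)
    cx, cy = simulate_intensities(frac_a_cdna, totals_c, cfg.noise_sd,
                                  cfg.dye_bias_coeffs, rng)

    # gDNA genotype calls with missingness; a few bad samples/SNPs exercise QC
    miss = rng.random((cfg.n_samples, n_snps)) < cfg.call_missing_rate
    if len(bad_snps):
        miss[:, bad_snps] |= rng.random((cfg.n_samples, len(bad_snps))) < cfg.bad_snp_missing_rate
    if cfg.n_bad_samples:
        bad_samples = rng.choice(cfg.n_samples, size=cfg.n_bad_samples, replace=False)
        miss[bad_samples, :] |= (
            rng.random((cfg.n_bad_samples, n_snps)) < cfg.bad_sample_missing_rate
        )
    call_strings = np.where(
        dosage_b == 0, "AA", np.where(dosage_b == 2, "BB", "AB")
    ).astype(object)
    calls = np.where(miss, None, call_strings)

    # cDNA calls: low call rate normally; contaminated samples call like gDNA
    cdna_rate = np.full(cfg.n_samples, cfg.base_cdna_call_rate)
    if cfg.n_contaminated:
        contaminated = rng.choice(cfg.n_samples, size=cfg.n_contaminated, replace=False)
        cdna_rate[contaminated] = cfg.contaminated_cdna_call_rate
    cdna_called = rng.random((cfg.n_samples, n_snps)) < cdna_rate[:, None]
    cdna_call_mat = np.where(cdna_called, call_strings, None)

    hap_strings = np.where(
        hap1 == 0, "A", "B"
    ).astype(object) + "|" + np.where(hap2 == 0, "A", "B").astype(object)

    def frame(arr, dtype=None):
        return pd.DataFrame(arr, index=sample_ids, columns=snp_ids)

    truth_pos = [
        (panel[j].chrom, panel[j].pos) for j in sorted(effect_snp_idx.values())
    ]
    span = ("chr1", 500_000, 1_000_000 + cfg.n_regions * cfg.region_spacing + 500_000)
    peaks = simulate_peaks(truth_pos, span, cfg, rng)

    catalog = _simulate_catalog(cfg, panel, truth, effect_snp_idx, region_of_snp, rng)

    return SimulatedData(
        config=cfg,
        panel=panel,
        regions=regions,
        gene_regions=gene_regions,
        haplotypes=frame(hap_strings),
        genotypes=frame(calls),
        cdna_calls=frame(cdna_call_mat),
        gdna_x=frame(gx),
        gdna_y=frame(gy),
        cdna_x=frame(cx),
        cdna_y=frame(cy),
        peaks=peaks,
        catalog=catalog,
        truth=truth,
    )


def _simulate_catalog(
    cfg: SimulationConfig,
    panel: list[SnpRecord],
    truth: pd.DataFrame,
    effect_snp_idx: dict[str, int],
    region_of_snp: np.ndarray,
    rng: np.random.Generator,
) -> list[GwasRecord]:
    """True cis-rSNP members plus panel-null and foreign decoy SNPs."""
    records: list[GwasRecord] = []
    used: set[str] = set()

    def pick_trait(immune_prob: float) -> tuple[str, bool]:
        immune = rng.random() < immune_prob
        pool = IMMUNE_TRAITS if immune else OTHER_TRAITS
        return pool[int(rng.integers(len(pool)))], immune

    for row in truth.itertuples(index=False):
        if not row.catalog_member:
            continue
        sid = row.true_cis_rsnp_id
        trait, immune = pick_trait(cfg.member_immune_prob)
        records.append(GwasRecord(sid, trait, immune))
        used.add(sid)

    effect_regions = {region_of_snp[j] for j in effect_snp_idx.values()}
    null_pool = [
        s.snp_id
        for j, s in enumerate(panel)
        if region_of_snp[j] not in effect_regions and s.snp_id not in used
    ]
    n_panel_decoys = min(cfg.n_catalog_decoys // 2, len(null_pool))
    for sid in rng.choice(null_pool, size=n_panel_decoys, replace=False):
        trait, immune = pick_trait(cfg.decoy_immune_prob)
        records.append(GwasRecord(str(sid), trait, immune))
    for k in range(cfg.n_catalog_decoys - n_panel_decoys):
        trait, immune = pick_trait(cfg.decoy_immune_prob)
        records.append(GwasRecord(f"rsX{k + 1:05d}", trait, immune))
    # deduplicate (snp_id, trait) pairs, keeping first occurrence
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        key = (r.snp_id, r.trait)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(data: SimulatedData, outdir: str | Path) -> None:
    """Write the complete input bundle + truth table as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aio.write_panel(data.panel, outdir / "panel.tsv")
    aio.write_regions(data.regions, outdir / "regions.bed")
    aio.write_regions(data.gene_regions, outdir / "gene_regions.bed")
    aio.write_matrix(data.haplotypes, outdir / "haplotypes.tsv")
    aio.write_matrix(data.genotypes, outdir / "genotypes.tsv")
    aio.write_matrix(data.cdna_calls, outdir / "cdna_calls.tsv")
    for name, df in (
        ("gdna_x", data.gdna_x), ("gdna_y", data.gdna_y),
        ("cdna_x", data.cdna_x), ("cdna_y", data.cdna_y),
    ):
        aio.write_matrix(df, outdir / f"{name}.tsv", float_format="%.4f")
    for mark, replicates in data.peaks.items():
        for r, peaks in enumerate(replicates):
            aio.write_peaks(peaks, outdir / f"peaks_{mark}_rep{r + 1}.bed")
    aio.write_gwas_catalog(data.catalog, outdir / "gwas_catalog.tsv")
    data.truth.to_csv(outdir / "truth_table.tsv", sep="\t", index=False,
                      float_format="%.6g")
    with open(outdir / "simulation_config.txt", "w") as fh:
        for k, v in sorted(vars(data.config).items()):
            fh.write(f"{k}\t{v}\n")


def simulate(cfg: SimulationConfig, outdir: str | Path) -> SimulatedData:
    data = simulate_bundle(cfg)
    write_bundle(data, outdir)
    return data
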