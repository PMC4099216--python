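"""Co-expression of cis-regulated lncRNAs with the closest protein-coding gene.

For each lncRNA region with a cis-rSNP, samples are split into the three
genotype groups of the most significantly associated SNP (AA, AB/BA pooled,
BB), coded 0/1/2, and the region's total expression (per-sample mean summed
raw cDNA signal) is regressed on the code; the same is done for the nearest
protein-coding gene's expression.  Pairs passing a Benjamini-Hochberg FDR of
10% are classified:

- co_regulated: the gene's own ASE is also significantly associated with the
  same cis-rSNP (p < 1e-6) — one variant drives both transcripts;
- lnc_only: the gene's ASE is evaluable but not associated — consistent with
  the lncRNA itself regulating the neighbour;
- unknown: the gene has no evaluable ASE window within 250 kb of the SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ase import AseWindow
from .association import ase_regression
from .io import RegionRecord

CATEGORIES = ("co_regulated", "lnc_only", "unknown")


@dataclass
class CoexpressionResult:
    region_id: str
    gene_id: str
    top_snp_id: str
    coexpr_p: float
    lnc_ase_p: float
    gene_ase_p: float | None
    category: str | None = None


def genotype_group_code(call: str) -> float:
    """Unphased genotype group: AA -> 0, AB/BA -> 1, BB -> 2, missing -> NaN."""
    if pd.isna(call):
        return float("nan")
    call = call.replace("|", "")
    if call in ("AA",):
        return 0.0
    if call in ("AB", "BA"):
        return 1.0
    if call in ("BB",):
        return 2.0
    raise ValueError(f"unrecognized genotype call {call!r}")


def genotype_group_expression_test(codes, expression) -> tuple[float, float]:
    """OLS slope and p of expression on the 0/1/2 genotype-group code.

    Same estimator and degenerate-case conventions as the ASE regression.
    """
    return ase_regression(codes, expression)


def bh_fdr(p_values, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns the indices of rejected hypotheses."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject)


def classify_pair(
    lnc_ase_p: float,
    gene_ase_p: float | None,
    gene_evaluable: bool,
    ase_p_thresh: float = 1e-6,
) -> str:
    """Three-way regulatory category for an FDR-passing pair."""
    if not gene_evaluable or gene_ase_p is None or np.isnan(gene_ase_p):
        return "unknown"
    if gene_ase_p < ase_p_thresh:
        return "co_regulated"
    return "lnc_only"


def nearest_gene(
    region: RegionRecord, genes: list[RegionRecord]
) -> RegionRecord | None:
    """Closest protein-coding region on the same chromosome (boundary distance).

    Ties broken by smaller gene start.  Distance 0 for overlapping regions.
    """
    best: tuple[int, int, RegionRecord] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        if g.end <= region.start:
            d = region.start - g.end + 1
        elif region.end <= g.start:
            d = g.start - region.end + 1
        else:
            d = 0
        key = (d, g.start)
        if best is None or key < (best[0], best[1]):
            best = (d, g.start, g)
    return best[2] if best else None


def region_expression_by_sample(
    snp_ids: list[str], cdna_x: pd.DataFrame, cdna_y: pd.DataFrame
) -> pd.Series:
    """Per-sample mean of summed raw cDNA channel signals over the region's SNPs."""
    ids = [s for s in snp_ids if s in cdna_x.columns]
    total = cdna_x[ids] + cdna_y[ids]
    return total.mean(axis=1, skipna=True)


def run_coexpression(
    lnc_windows: list[AseWindow],
    gene_windows: list[AseWindow],
    associations: pd.DataFrame,
    genotypes: pd.DataFrame,
    cdna_x: pd.DataFrame,
    cdna_y: pd.DataFrame,
    gene_regions: list[RegionRecord],
    fdr_q: float = 0.10,
    ase_p_thresh: float = 1e-6,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Coexpression table for every lncRNA window with a significant cis-rSNP."""
    sig = associations[associations["significant"]]
    gene_window_by_id = {w.region.region_id: w for w in gene_windows}
    gene_assoc = associations.set_index(["region_id", "snp_id"])["p_value"] \
        if len(associations) else pd.Series(dtype=float)

    results: list[CoexpressionResult] = []
    for w in lnc_windows:
        rows = sig[sig["region_id"] == w.region.region_id]
        if rows.empty:
            continue
        top = rows.loc[rows["p_value"].idxmin()]
        gene = nearest_gene(w.region, gene_regions)
        if gene is None:
            continue
        # expression ~ genotype group at the top cis-rSNP, for both transcripts
        codes = genotypes[top["snp_id"]].map(genotype_group_code) \
            if top["snp_id"] in genotypes.columns else None
        if codes is None:
            continue
        lnc_expr = region_expression_by_sample(
            [s.snp_id for s in w.informative_snps], cdna_x, cdna_y)
        gene_w = gene_window_by_id.get(gene.region_id)
        gene_snp_ids = [s.snp_id for s in gene_w.informative_snps] if gene_w else []
        if not gene_snp_ids:
            continue
        gene_expr = region_expression_by_sample(gene_snp_ids, cdna_x, cdna_y)
        try:
            _, coexpr_p = genotype_group_expression_test(codes, gene_expr)
        except ValueError:
            continue
        # gene ASE is evaluable iff the gene has a passing window and its own
        # association test for the same SNP (SNP within the gene's window span)
        gene_ase_p: float | None = None
        evaluable = False
        if gene_w is not None and gene_w.passed:
            key = (gene.region_id, top["snp_id"])
            if key in gene_assoc.index:
                gene_ase_p = float(gene_assoc.loc[key])
                evaluable = True
        results.append(
            CoexpressionResult(
                region_id=w.region.region_id,
                gene_id=gene.region_id,
                top_snp_id=str(top["snp_id"]),
                coexpr_p=float(coexpr_p),
                lnc_ase_p=float(top["p_value"]),
                gene_ase_p=gene_ase_p,
            )
        )

    df = pd.DataFrame(
        [vars(r) for r in results],
        columns=["region_id", "gene_id", "top_snp_id", "coexpr_p",
                 "lnc_ase_p", "gene_ase_p", "category"],
    )
    if df.empty:
        df["fdr_pass"] = pd.Series(dtype=bool)
        return df
    rejected = bh_fdr(df["coexpr_p"].to_numpy(), q=fdr_q)
    df["fdr_pass"] = False
    df.loc[df.index[rejected], "fdr_pass"] = True
    df["category"] = [
        classify_pair(r.lnc_ase_p, r.gene_ase_p,
                      r.gene_ase_p is not None and not pd.isna(r.gene_ase_p),
                      ase_p_thresh)
        if fp else None
        for r, fp in zip(df.itertuples(index=False), df["fdr_pass"])
    ]
    return df
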