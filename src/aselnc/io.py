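"""Readers and writers for the tabular and interval formats of the pipeline.

Coordinate conventions are enforced at these boundaries and nowhere else:
interval files (regions, peaks) are BED, 0-based half-open; SNP positions in
the panel TSV are 1-based.  Missing values in TSV matrices are written as
``NA`` — never 0, because 0 is a legal fluorescence intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_MARKS = ("H3K27ac", "H3K4me1")
VALID_REGION_CLASSES = ("intergenic", "genic", "protein_coding")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 1-based
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"SNP {self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class RegionRecord:
    region_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    region_class: str = "intergenic"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.region_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.region_class not in VALID_REGION_CLASSES:
            raise ValidationError(
                f"region {self.region_id}: unknown class {self.region_class!r}"
            )

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    mark: str
    replicate_id: str
    peak_p: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not (0.0 < self.peak_p <= 1.0):
            raise ValidationError(f"peak p-value must be in (0,1], got {self.peak_p}")
        if self.mark not in VALID_MARKS:
            raise ValidationError(f"unknown histone mark {self.mark!r}")


@dataclass(frozen=True)
class GwasRecord:
    snp_id: str
    trait: str
    immune_related: bool


# ---------------------------------------------------------------------------
# Region BED I/O


def read_regions(path: str | Path) -> list[RegionRecord]:
    """Read regions from BED3+ (name column = region_id, optional class column).

    Intervals are returned 0-based half-open exactly as stored in BED.
    Duplicate region ids are rejected.
    """
    regions: list[RegionRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, region_id = fields[:4]
            region_class = fields[4] if len(fields) >= 5 else "intergenic"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if region_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate region_id {region_id!r}")
            seen.add(region_id)
            try:
                regions.append(RegionRecord(region_id, chrom, start, end, region_class))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[RegionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.region_class}\n")


# ---------------------------------------------------------------------------
# Peak BED I/O (BED3+ with mark, replicate and peak p-value columns)


def read_peaks(path: str | Path) -> list[PeakRecord]:
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns (chrom start end mark replicate p)"
                )
            chrom, start_s, end_s, mark, rep, p_s = fields[:6]
            try:
                start, end, p = int(start_s), int(end_s), float(p_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            try:
                peaks.append(PeakRecord(chrom, start, end, mark, rep, p))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.mark}\t{p.replicate_id}\t{p.peak_p:.6g}\n"
            )


# ---------------------------------------------------------------------------
# SNP panel

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


def read_panel(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: panel missing columns {missing}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValidationError(f"{path}: duplicate snp_ids {dups[:5]}")
    return [
        SnpRecord(str(r.snp_id), str(r.chrom), int(r.pos), str(r.allele_a), str(r.allele_b))
        for r in df.itertuples(index=False)
    ]


def write_panel(panel: Iterable[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for s in panel:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.allele_a}\t{s.allele_b}\n")


# ---------------------------------------------------------------------------
# Sample x SNP matrices (numeric intensities or string calls)


def _check_rectangular(path: str | Path) -> None:
    with open(path) as fh:
        header = fh.readline()
        ncol = header.count("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            nfields = line.count("\t") + 1
            if nfields != ncol + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({nfields} fields, expected {ncol + 1})"
                )


def read_matrix(
    path: str | Path,
    panel: Sequence[SnpRecord] | None = None,
    numeric: bool = True,
) -> pd.DataFrame:
    """Read a sample x SNP TSV matrix (header = SNP ids, first column = sample ids).

    ``NA`` cells become missing (NaN for numeric, pd.NA for calls), never zero.
    If a panel is given, every column must be a panel SNP.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False, low_memory=False)
    try:
        df = df.astype(float if numeric else "string")
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell in numeric matrix ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if panel is not None:
        panel_ids = {s.snp_id for s in panel}
        unknown = [c for c in df.columns if c not in panel_ids]
        if unknown:
            raise ValidationError(f"{path}: SNP ids absent from panel: {unknown[:10]}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=float_format, index_label="sample")


# ---------------------------------------------------------------------------
# GWAS catalog


def read_gwas_catalog(path: str | Path) -> list[GwasRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = ["snp_id", "trait", "immune_related"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: catalog missing columns {missing}")
    if df.duplicated(subset=["snp_id", "trait"]).any():
        raise ValidationError(f"{path}: duplicate (snp_id, trait) pairs")
    return [
        GwasRecord(str(r.snp_id), str(r.trait), bool(r.immune_related))
        for r in df.itertuples(index=False)
    ]


def write_gwas_catalog(records: Iterable[GwasRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\ttrait\timmune_related\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.trait}\t{str(r.immune_related)}\n")
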