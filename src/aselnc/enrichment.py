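"""Replicate-consensus enhancer peaks and cis-rSNP fold enrichment.

ChIP-seq peaks (H3K27ac: active enhancers; H3K4me1: poised enhancers) from
replicate samples are reconciled into consensus peaks: a peak counts only if
its MACS-style p-value passes 1e-5 and peaks covering it in at least two of
the replicates (itself included) overlap it by more than 50% of the shorter
peak.  Enrichment compares the fraction of significant cis-rSNPs falling in
peaks against the fraction of clearly non-significant SNPs (association
p > 0.5) in peaks, with a two-sided Fisher's exact test on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import PeakRecord


@dataclass(frozen=True)
class ConsensusPeak:
    chrom: str
    start: int  # 0-based half-open
    end: int
    mark: str
    n_support: int


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _supports(a: PeakRecord, b: PeakRecord, min_overlap: float) -> bool:
    """True iff the nucleotide overlap exceeds min_overlap of the SHORTER peak."""
    ov = _overlap_len(a.start, a.end, b.start, b.end)
    shorter = min(a.end - a.start, b.end - b.start)
    return ov > min_overlap * shorter


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping or touching (chrom, start, end) intervals."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def consensus_peaks(
    replicate_peaks: list[list[PeakRecord]],
    min_support: int = 2,
    min_overlap: float = 0.5,
    peak_p_thresh: float = 1e-5,
) -> list[ConsensusPeak]:
    """Reconcile replicate peak sets of one mark into merged consensus peaks.

    Invariant under replicate ordering; raising min_support can only shrink
    the result.
    """
    if len(replicate_peaks) < min_support:
        raise ValueError(
            f"need >= min_support={min_support} replicate sets, got {len(replicate_peaks)}"
        )
    for i, peaks in enumerate(replicate_peaks):
        if not peaks:
            raise ValueError(f"replicate set {i} is empty")

    filtered = [[p for p in peaks if p.peak_p <= peak_p_thresh] for peaks in replicate_peaks]
    marks = {p.mark for peaks in filtered for p in peaks}
    if len(marks) > 1:
        raise ValueError(f"consensus_peaks expects one mark per call, got {sorted(marks)}")

    trees: list[dict[str, IntervalTree]] = []
    for peaks in filtered:
        by_chrom: dict[str, IntervalTree] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        trees.append(by_chrom)

    kept: list[tuple[str, int, int, int]] = []  # (chrom, start, end, support)
    for ri, peaks in enumerate(filtered):
        for p in peaks:
            support = 0
            for rj, by_chrom in enumerate(trees):
                if rj == ri:
                    support += 1  # a peak always supports itself
                    continue
                tree = by_chrom.get(p.chrom)
                if tree is None:
                    continue
                hits = tree.overlap(p.start, p.end)
                if any(_supports(p, iv.data, min_overlap) for iv in hits):
                    support += 1
            if support >= min_support:
                kept.append((p.chrom, p.start, p.end, support))

    mark = next(iter(marks)) if marks else "H3K27ac"
    out: list[ConsensusPeak] = []
    for chrom, start, end, support in sorted(kept):
        if out and out[-1].chrom == chrom and start <= out[-1].end:
            prev = out[-1]
            out[-1] = ConsensusPeak(chrom, prev.start, max(prev.end, end), mark,
                                    max(prev.n_support, support))
        else:
            out.append(ConsensusPeak(chrom, start, end, mark, support))
    return out


def flank(
    peaks: list[ConsensusPeak], pad: int = 2500
) -> list[tuple[str, int, int]]:
    """Pad each consensus peak ``pad`` bp both sides, clip at 0, merge."""
    padded = [(p.chrom, max(0, p.start - pad), p.end + pad) for p in peaks]
    return merge_intervals(padded)


class IntervalSet:
    """Sorted non-overlapping intervals with a vectorized point-membership query."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_intervals(list(intervals))
        for chrom in {c for c, _, _ in merged}:
            ivs = [(s, e) for c, s, e in merged if c == chrom]
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            self._by_chrom[chrom] = (starts, ends)

    @classmethod
    def from_peaks(cls, peaks: list[ConsensusPeak]) -> "IntervalSet":
        return cls([(p.chrom, p.start, p.end) for p in peaks])

    def contains_positions(self, chroms, positions_1based) -> np.ndarray:
        """Membership of 1-based SNP positions (converted to 0-based points)."""
        chroms = np.asarray(chroms)
        pos0 = np.asarray(positions_1based, dtype=int) - 1
        out = np.zeros(pos0.shape, dtype=bool)
        for chrom, (starts, ends) in self._by_chrom.items():
            m = chroms == chrom
            if not m.any():
                continue
            idx = np.searchsorted(starts, pos0[m], side="right") - 1
            ok = idx >= 0
            inside = np.zeros(m.sum(), dtype=bool)
            inside[ok] = pos0[m][ok] < ends[idx[ok]]
            out[m] = inside
        return out


def fold_enrichment(
    sig_positions: list[tuple[str, int]],
    nonsig_positions: list[tuple[str, int]],
    intervals: IntervalSet,
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Fold = (sig in-peak fraction)/(nonsig in-peak fraction) with Fisher p.

    Positions are (chrom, 1-based pos).  Returns (fold, two-sided Fisher p,
    (sig_in, sig_out, nonsig_in, nonsig_out)).
    """
    if not sig_positions or not nonsig_positions:
        raise ValueError("both SNP sets must be nonempty")
    sig_in = int(intervals.contains_positions(
        [c for c, _ in sig_positions], [p for _, p in sig_positions]).sum())
    non_in = int(intervals.contains_positions(
        [c for c, _ in nonsig_positions], [p for _, p in nonsig_positions]).sum())
    sig_out = len(sig_positions) - sig_in
    non_out = len(nonsig_positions) - non_in
    frac_sig = sig_in / len(sig_positions)
    frac_non = non_in / len(nonsig_positions)
    if frac_non == 0.0:
        import warnings

        warnings.warn("non-significant in-peak fraction is 0; fold is infinite",
                      stacklevel=2)
        fold = float("inf") if frac_sig > 0 else float("nan")
    else:
        fold = frac_sig / frac_non
    _, fisher_p = stats.fisher_exact(
        [[sig_in, sig_out], [non_in, non_out]], alternative="two-sided"
    )
    return fold, float(fisher_p), (sig_in, sig_out, non_in, non_out)
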