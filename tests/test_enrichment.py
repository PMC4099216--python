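import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.stats import hypergeom

from aselnc.enrichment import (
    ConsensusPeak,
    IntervalSet,
    consensus_peaks,
    flank,
    fold_enrichment,
    merge_intervals,
)
from aselnc.io import PeakRecord


def _peak(start, end, mark="H3K27ac", rep="rep1", p=1e-8):
    return PeakRecord("chr1", start, end, mark, rep, p)


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric probabilities <= the observed table's probability."""
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, row1, col1)
        if pk <= obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestConsensus:
    def test_two_of_four_identical_retained(self):
        reps = [
            [_peak(100, 1100)],
            [_peak(100, 1100)],
            [_peak(9000, 9500)],
            [_peak(5000, 5400)],
        ]
        cons = consensus_peaks(reps, min_support=2)
        spans = {(c.start, c.end) for c in cons}
        assert (100, 1100) in spans
        assert (9000, 9500) not in spans and (5000, 5400) not in spans

    def test_exactly_half_overlap_is_not_support(self):
        # two 1000-bp peaks overlapping by exactly 500 bp: not mutual support
        reps = [
            [_peak(0, 1000)],
            [_peak(500, 1500)],
            [_peak(90000, 91000)],
            [_peak(95000, 96000)],
        ]
        assert consensus_peaks(reps, min_support=2) == []

    def test_just_over_half_overlap_is_support(self):
        reps = [[_peak(0, 1000)], [_peak(499, 1499)]]
        cons = consensus_peaks(reps, min_support=2)
        assert len(cons) == 1
        assert cons[0].start == 0 and cons[0].end == 1499

    def test_weak_peaks_dropped_before_support(self):
        reps = [[_peak(0, 1000, p=1e-3)], [_peak(0, 1000)]]
        assert consensus_peaks(reps, min_support=2) == []

    def test_invariant_under_replicate_order(self):
        reps = [
            [_peak(0, 1000), _peak(5000, 5800)],
            [_peak(100, 1050)],
            [_peak(4900, 5700)],
            [_peak(80000, 80500)],
        ]
        base = consensus_peaks(reps, min_support=2)
        for perm in itertools.permutations(reps):
            assert consensus_peaks(list(perm), min_support=2) == base

    def test_raising_min_support_is_monotone(self):
        rng = np.random.default_rng(5)
        reps = []
        for r in range(4):
            peaks = []
            for c in rng.integers(0, 200_000, 60):
                peaks.append(_peak(int(c), int(c) + int(rng.integers(300, 1500))))
            reps.append(peaks)
        counts = [
            len(consensus_peaks(reps, min_support=s)) for s in (2, 3, 4)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            consensus_peaks([[_peak(0, 100)], []])


class TestFlank:
    def test_pad_clip_merge(self):
        peaks = [ConsensusPeak("chr1", 1000, 2000, "H3K27ac", 2)]
        assert flank(peaks, 2500) == [("chr1", 0, 4500)]

    def test_nearby_peaks_merge_after_padding(self):
        peaks = [
            ConsensusPeak("chr1", 10_000, 11_000, "H3K27ac", 2),
            ConsensusPeak("chr1", 15_000, 16_000, "H3K27ac", 2),
        ]
        assert flank(peaks, 2500) == [("chr1", 7500, 18_500)]

    def test_empty(self):
        assert flank([], 2500) == []


def test_merge_intervals():
    ivs = [("chr1", 10, 20), ("chr1", 15, 30), ("chr2", 0, 5), ("chr1", 40, 50)]
    assert merge_intervals(ivs) == [("chr1", 10, 30), ("chr1", 40, 50), ("chr2", 0, 5)]


def test_interval_set_point_membership():
    s = IntervalSet([("chr1", 100, 200)])
    # 1-based position 101 -> 0-based 100 (inside); 1-based 100 -> 99 (outside)
    assert s.contains_positions(["chr1"], [101])[0]
    assert not s.contains_positions(["chr1"], [100])[0]
    assert s.contains_positions(["chr1"], [200])[0]
    assert not s.contains_positions(["chr1"], [201])[0]
    assert not s.contains_positions(["chr2"], [150])[0]


class TestFoldEnrichment:
    def test_reported_fraction_pair(self):
        """In-peak fractions 12.5% vs 8.1% give a 1.54-fold enrichment (2 dp)."""
        peaks = IntervalSet([("chr1", 0, 1000)])
        sig = [("chr1", 500)] * 125 + [("chr1", 5000)] * 875
        nonsig = [("chr1", 500)] * 81 + [("chr1", 5000)] * 919
        fold, p, _ = fold_enrichment(sig, nonsig, peaks)
        assert round(fold, 2) == 1.54

    def test_two_by_two_against_hypergeometric_oracle(self):
        peaks = IntervalSet([("chr1", 0, 1000)])
        sig = [("chr1", 500)] * 10 + [("chr1", 5000)] * 90
        nonsig = [("chr1", 500)] * 20 + [("chr1", 5000)] * 380
        fold, p, tab = fold_enrichment(sig, nonsig, peaks)
        assert fold == pytest.approx(2.0)
        assert tab == (10, 90, 20, 380)
        assert p == pytest.approx(fisher_two_sided_oracle(10, 90, 20, 380), abs=1e-10)

    def test_identical_sets_no_enrichment(self):
        peaks = IntervalSet([("chr1", 0, 1000)])
        pts = [("chr1", 500)] * 5 + [("chr1", 5000)] * 5
        fold, p, _ = fold_enrichment(pts, pts, peaks)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_nonsig_fraction_warns_infinite(self):
        peaks = IntervalSet([("chr1", 0, 1000)])
        sig = [("chr1", 500)] * 3 + [("chr1", 5000)] * 7
        nonsig = [("chr1", 5000)] * 10
        with pytest.warns(UserWarning, match="infinite"):
            fold, _, _ = fold_enrichment(sig, nonsig, peaks)
        assert np.isinf(fold)

    def test_empty_class_rejected(self):
        peaks = IntervalSet([("chr1", 0, 1000)])
        with pytest.raises(ValueError):
            fold_enrichment([], [("chr1", 5)], peaks)


def test_fisher_matches_enumeration_on_small_tables():
    """scipy's two-sided Fisher equals brute-force enumeration for all margins <= 12."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 13, 4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(
            fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-10
        )


def test_random_peaks_give_null_fold(rng):
    """Uniformly placed peaks show no enrichment: median fold within [0.8, 1.25]."""
    folds = []
    for _ in range(100):
        starts = rng.integers(0, 1_000_000, 60)
        peaks = IntervalSet([("chr1", int(s), int(s) + 2000) for s in starts])
        sig = [("chr1", int(p)) for p in rng.integers(1, 1_000_000, 150)]
        nonsig = [("chr1", int(p)) for p in rng.integers(1, 1_000_000, 600)]
        try:
            fold, _, _ = fold_enrichment(sig, nonsig, peaks)
        except ValueError:
            continue
        if np.isfinite(fold) and fold > 0:
            folds.append(fold)
    med = float(np.median(folds))
    assert 0.8 <= med <= 1.25
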