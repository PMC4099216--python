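import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aselnc.association import (
    AssociationResult,
    ase_regression,
    candidate_snps,
    genotype_code,
    ld_pruned_test_count,
    ld_r2,
    significance_filter,
    slope_to_percent_diff,
)
from aselnc.io import RegionRecord, SnpRecord


def _ols_oracle(x, y):
    """Independent closed-form OLS + t-test, straight from the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    slope = (xc * yc).sum() / (xc * xc).sum()
    resid = yc - slope * xc
    se = math.sqrt((resid ** 2).sum() / (n - 2) / (xc * xc).sum())
    if se == 0.0:
        return slope, 0.0  # perfect fit; callers treat this as degenerate
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, p


class TestCandidateSnps:
    region = RegionRecord("R1", "chr2", 999_999, 1_020_000)  # 1-based 1e6..1.02e6

    def _snp(self, pos):
        return SnpRecord(f"rs{pos}", "chr2", pos, "A", "B")

    def test_window_boundaries_inclusive(self):
        panel = [
            self._snp(750_000),  # exactly 250 kb upstream of start
            self._snp(749_999),  # 250001 bp away
            self._snp(1_010_000),  # inside
            self._snp(1_270_000),  # exactly 250 kb downstream of end
            self._snp(1_270_001),
        ]
        got = {s.pos for s in candidate_snps(self.region, panel)}
        assert got == {750_000, 1_010_000, 1_270_000}

    def test_other_chromosome_excluded(self):
        panel = [SnpRecord("rsX", "chr3", 1_010_000, "A", "B")]
        assert candidate_snps(self.region, panel) == []


class TestGenotypeCode:
    @pytest.mark.parametrize(
        "call,code",
        [("A|A", 0.0), ("B|B", 0.0), ("A|B", 1.0), ("B|A", -1.0)],
    )
    def test_codes(self, call, code):
        assert genotype_code(call) == code

    def test_missing_is_nan(self):
        assert np.isnan(genotype_code(None))
        assert np.isnan(genotype_code(float("nan")))


class TestAseRegression:
    def test_frozen_closed_form_example(self):
        # x_bar = 0, sum x^2 = 4, sum xy = 0.65 -> slope 0.1625
        codes = [-1, -1, 0, 0, 1, 1]
        ase = [-0.1, -0.2, 0.0, 0.05, 0.15, 0.2]
        slope, p = ase_regression(codes, ase)
        assert slope == pytest.approx(0.1625, abs=1e-12)
        o_slope, o_p = _ols_oracle(codes, ase)
        assert slope == pytest.approx(o_slope, rel=1e-12)
        assert p == pytest.approx(o_p, rel=1e-12)

    def test_noiseless_effect_recovered_exactly(self):
        codes = np.tile([-1, 0, 1], 8)
        slope, p = ase_regression(codes, 0.2 * codes)
        assert slope == pytest.approx(0.2)
        assert p <= 1e-300  # machine floor for a perfect fit

    def test_all_zero_ase_convention(self):
        codes = [-1, 0, 1, -1, 0, 1]
        slope, p = ase_regression(codes, np.zeros(6))
        assert slope == 0.0 and p == 1.0

    def test_constant_codes_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ase_regression(np.zeros(6), np.arange(6.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ase_regression([0, 1], [0.0, 0.1])

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_oracle_to_12_digits(self, data):
        n = data.draw(st.integers(6, 30))
        codes = data.draw(
            st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=n, max_size=n)
        )
        if len(set(codes)) < 2:
            return
        ase = data.draw(
            st.lists(
                st.floats(-0.5, 0.5, allow_nan=False), min_size=n, max_size=n
            )
        )
        slope, p = ase_regression(codes, ase)
        o_slope, o_p = _ols_oracle(codes, ase)
        if abs(o_slope) < 1e-12 or o_p < 1e-290:
            return  # oracle in its own degenerate regime
        assert slope == pytest.approx(o_slope, rel=1e-12)
        assert p == pytest.approx(o_p, rel=1e-9)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_negating_codes_negates_slope_only(self, data):
        n = data.draw(st.integers(6, 20))
        codes = np.array(
            data.draw(st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=n, max_size=n))
        )
        if len(set(codes.tolist())) < 2:
            return
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
        ase = rng.normal(0, 0.1, n)
        s1, p1 = ase_regression(codes, ase)
        s2, p2 = ase_regression(-codes, ase)
        assert s1 == pytest.approx(-s2, rel=1e-12, abs=1e-15)
        assert p1 == pytest.approx(p2, rel=1e-12)
        # permuting samples changes nothing
        perm = rng.permutation(n)
        s3, p3 = ase_regression(codes[perm], ase[perm])
        assert s1 == pytest.approx(s3, rel=1e-12)
        assert p1 == pytest.approx(p3, rel=1e-12)


class TestSignificanceFilter:
    def _res(self, p, slope, n_ab, n_ba, n_hom):
        return AssociationResult("R", "rs", 0, slope, p, n_ab, n_ba, n_hom, False)

    def test_published_thresholds(self):
        assert significance_filter(self._res(1e-7, 0.06, 5, 5, 20))
        assert not significance_filter(self._res(1e-7, 0.04, 5, 5, 20))
        assert not significance_filter(self._res(1e-5, 0.06, 5, 5, 20))
        assert not significance_filter(self._res(1e-7, 0.06, 3, 10, 20))
        assert not significance_filter(self._res(1e-7, 0.06, 10, 10, 3))
        # boundaries: slope exactly 0.05 passes, p exactly 1e-6 fails
        assert significance_filter(self._res(9.9e-7, 0.05, 4, 4, 4))
        assert not significance_filter(self._res(1e-6, 0.05, 4, 4, 4))


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([1, 0, 1, 1, 0])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_frozen_hand_example(self):
        # pairs (1,1),(1,1),(0,0),(0,1): D = 0.5 - 0.5*0.75 = 0.125 -> r2 = 1/3
        a = [1, 1, 0, 0]
        b = [1, 1, 0, 1]
        assert ld_r2(a, b) == pytest.approx(1 / 3, abs=1e-12)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 0]))

    def test_independent_loci_near_zero(self, rng):
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert ld_r2(a, b) < 0.01


def test_slope_to_percent_diff():
    assert slope_to_percent_diff(0.05) == pytest.approx(20.0)
    assert slope_to_percent_diff(0.0) == 0.0
    assert slope_to_percent_diff(0.25) == pytest.approx(100.0)
    with pytest.warns(UserWarning):
        assert slope_to_percent_diff(0.6) == 200.0
    with pytest.raises(ValueError):
        slope_to_percent_diff(-0.1)


def test_ld_pruning_counts_unique_signals(rng):
    n = 400
    a = rng.integers(0, 2, n).astype(float)
    b = a.copy()  # r2 = 1 with a
    c = rng.integers(0, 2, n).astype(float)
    haps = pd.DataFrame({"rs1": a, "rs2": b, "rs3": c})
    assert ld_pruned_test_count(["rs1", "rs2", "rs3"], haps, r2_thresh=0.9) == 2


def test_type_one_error_calibrated(rng):
    """Null ASE regressions reject at ~5%: inside the binomial 99% interval."""
    n_tests, n = 4000, 100
    codes = rng.choice([-1.0, 0.0, 1.0], size=(n_tests, n), p=[0.2, 0.6, 0.2])
    ase = rng.normal(0, 0.05, size=(n_tests, n))
    rejections = 0
    for i in range(n_tests):
        if len(set(codes[i])) < 2:
            continue
        _, p = ase_regression(codes[i], ase[i])
        rejections += p < 0.05
    lo, hi = stats.binom.interval(0.99, n_tests, 0.05)
    assert lo <= rejections <= hi
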