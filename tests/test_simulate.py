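import filecmp

import numpy as np
import pandas as pd
import pytest

from aselnc.qc import hwe_chisq
from aselnc.association import ld_r2
from aselnc.simulate import (
    SimulationConfig,
    _build_layout,
    simulate_bundle,
    simulate_haplotypes,
    simulate_intensities,
    simulate_peaks,
    write_bundle,
)


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimulationConfig()  # no seed


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, cis_effect_fraction=1.5)


class TestHaplotypes:
    def _blocks(self, n_snps, block_size):
        return [list(range(i, min(i + block_size, n_snps)))
                for i in range(0, n_snps, block_size)]

    def test_independent_snps_have_no_ld(self):
        rng = np.random.default_rng(1)
        haps, _ = simulate_haplotypes(
            5000, self._blocks(10, 5), 10, (0.3, 0.5), 0.0, rng)
        for j in range(4):
            r2 = ld_r2(haps[:, j], haps[:, j + 1])
            assert r2 < 0.01

    def test_perfect_block_ld(self):
        rng = np.random.default_rng(2)
        haps, p_b = simulate_haplotypes(
            2000, self._blocks(4, 4), 4, (0.4, 0.4), 1.0, rng)
        # identical frequencies + rho=1 -> identical latent -> r2 = 1
        for j in range(3):
            assert ld_r2(haps[:, j], haps[:, j + 1]) == pytest.approx(1.0)

    def test_genotypes_obey_hardy_weinberg(self):
        rng = np.random.default_rng(3)
        n_snps = 10_000
        haps, _ = simulate_haplotypes(
            500, self._blocks(n_snps, 20), n_snps, (0.1, 0.5), 0.6, rng)
        g = haps[0::2] + haps[1::2]
        bad = 0
        for j in range(n_snps):
            n_bb = int((g[:, j] == 2).sum())
            n_ab = int((g[:, j] == 1).sum())
            n_aa = int((g[:, j] == 0).sum())
            if hwe_chisq(n_aa, n_ab, n_bb)[1] < 1e-6:
                bad += 1
        assert bad / n_snps <= 1e-3


class TestIntensities:
    def test_no_noise_no_bias_reproduces_fractions(self):
        rng = np.random.default_rng(4)
        frac = np.array([[0.6, 0.0, 1.0]])
        totals = np.full((1, 3), 2000.0)
        x, y = simulate_intensities(frac, totals, 0.0, None, rng)
        np.testing.assert_allclose(x / (x + y), frac)
        np.testing.assert_allclose(x + y, totals)

    def test_channel_sum_conserved_within_noise(self):
        rng = np.random.default_rng(5)
        frac = np.full((200, 50), 0.5)
        totals = 10 ** rng.normal(3.5, 0.25, size=(200, 50))
        x, y = simulate_intensities(frac, totals, 0.05, None, rng)
        assert np.all(x >= 0) and np.all(y >= 0)
        rel = (x + y) / totals - 1
        assert abs(rel.mean()) < 0.01
        assert rel.std() == pytest.approx(np.sqrt(2) * 0.05, rel=0.1)

    def test_dye_bias_inflates_x_channel(self):
        rng = np.random.default_rng(6)
        frac = np.full((100, 100), 0.5)
        totals = np.full((100, 100), 3000.0)
        x, y = simulate_intensities(frac, totals, 0.0, (0.3, 4.0), rng)
        g = 1 + 0.3 * np.log10(3000.0) / 4
        np.testing.assert_allclose(x / y, g, rtol=1e-9)


class TestPeaks:
    cfg = SimulationConfig(seed=9, n_regions=10)

    def test_all_replicates_no_jitter_reproduce_placed_peaks(self):
        cfg = SimulationConfig(
            seed=9, peak_rep_inclusion=1.0, peak_jitter_sd=0.0,
            peak_weak_fraction=0.0)
        rng = np.random.default_rng(0)
        peaks = simulate_peaks([("chr1", 5000)], ("chr1", 0, 100_000), cfg, rng)
        for mark, reps in peaks.items():
            spans0 = [(p.start, p.end) for p in reps[0]]
            for r in reps[1:]:
                assert [(p.start, p.end) for p in r] == spans0

    def test_null_odds_add_no_extra_peaks(self):
        cfg = SimulationConfig(seed=9, peak_enrichment_odds=1.0)
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        with_truth = simulate_peaks(
            [("chr1", int(p)) for p in range(10_000, 500_000, 10_000)],
            ("chr1", 0, 1_000_000), cfg, rng1)
        without = simulate_peaks([], ("chr1", 0, 1_000_000), cfg, rng2)
        n_with = sum(len(r) for r in with_truth["H3K4me1"])
        n_without = sum(len(r) for r in without["H3K4me1"])
        assert n_with == n_without

    def test_enriched_odds_detected_by_fold(self, rng):
        """odds=3 yields measurable fold enrichment of truth SNPs in peaks."""
        from aselnc.enrichment import IntervalSet, consensus_peaks, fold_enrichment

        cfg = SimulationConfig(seed=1, peak_enrichment_odds=3.0)
        truth_pos = [("chr1", int(p)) for p in rng.integers(1, 5_000_000, 400)]
        null_pos = [("chr1", int(p)) for p in rng.integers(1, 5_000_000, 4600)]
        peaks = simulate_peaks(truth_pos, ("chr1", 0, 5_000_000), cfg,
                               np.random.default_rng(11))
        cons = consensus_peaks(peaks["H3K4me1"], 2, 0.5, 1e-5)
        fold, fisher_p, _ = fold_enrichment(
            truth_pos, null_pos, IntervalSet.from_peaks(cons))
        assert fold > 1.3
        assert fisher_p < 0.01


class TestBundle:
    def test_truth_table_covers_every_region(self, small_bundle_data):
        truth = small_bundle_data.truth
        ids = {r.region_id for r in small_bundle_data.regions}
        assert set(truth["region_id"]) == ids
        assert not truth["region_id"].duplicated().any()

    def test_effect_construction_shifts_het_cdna_fraction(self):
        """Without noise/bias, het cDNA fractions sit at the configured 0.6."""
        cfg = SimulationConfig(
            seed=21, n_regions=12, cis_effect_fraction=1.0, noise_sd=0.0,
            dye_bias_coeffs=(0.0, 4.0), call_missing_rate=0.0,
            bad_snp_fraction=0.0, hwe_violation_fraction=0.0, n_bad_samples=0,
        )
        data = simulate_bundle(cfg)
        truth = data.truth.set_index("region_id")
        frac = data.cdna_x / (data.cdna_x + data.cdna_y)
        layout = {r.region_id: r for r in data.regions}
        checked = 0
        for region_id, row in truth.iterrows():
            esnp = row["true_cis_rsnp_id"]
            if esnp == "NA":
                continue
            region = layout[region_id]
            in_region = [s.snp_id for s in data.panel
                         if s.chrom == region.chrom and region.contains_pos(s.pos)]
            carriers = data.genotypes[esnp] == "AB"
            for sid in in_region:
                het = data.genotypes[sid] == "AB"
                sel = het & carriers
                if sel.any():
                    f = frac.loc[sel, sid]
                    assert np.allclose(np.abs(f - 0.5), 0.1, atol=1e-9)
                    checked += 1
        assert checked > 10

    def test_homozygous_cdna_fraction_unaffected_by_effect(self):
        cfg = SimulationConfig(
            seed=22, n_regions=6, cis_effect_fraction=1.0, noise_sd=0.0,
            dye_bias_coeffs=(0.0, 4.0))
        data = simulate_bundle(cfg)
        frac = data.cdna_x / (data.cdna_x + data.cdna_y)
        hom_a = (data.genotypes == "AA").to_numpy()
        hom_b = (data.genotypes == "BB").to_numpy()
        f = frac.to_numpy()
        assert np.allclose(f[hom_a], 1.0)
        assert np.allclose(f[hom_b], 0.0)

    def test_byte_identical_bundles_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=77, n_regions=6)
        write_bundle(simulate_bundle(cfg), tmp_path / "a")
        write_bundle(simulate_bundle(SimulationConfig(seed=77, n_regions=6)),
                     tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert not mismatch and not errors

    def test_different_seed_changes_output(self, tmp_path):
        a = simulate_bundle(SimulationConfig(seed=1, n_regions=4))
        b = simulate_bundle(SimulationConfig(seed=2, n_regions=4))
        assert not a.gdna_x.equals(b.gdna_x)

    def test_flank_snps_stay_outside_transcribed_intervals(self, small_bundle_data):
        data = small_bundle_data
        transcribed = {r.region_id: r for r in data.regions}
        transcribed.update({r.region_id: r for r in data.gene_regions})
        truth = data.truth
        # SNPs inside any lnc/gene interval must be the intended region SNPs:
        # count per region == snps_per_region exactly
        for region in list(data.regions) + list(data.gene_regions):
            inside = [s for s in data.panel
                      if s.chrom == region.chrom and region.contains_pos(s.pos)]
            assert len(inside) == data.config.snps_per_region
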