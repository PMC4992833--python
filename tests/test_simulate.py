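"""Synthetic WGA-bias generator: truth rasterization, count and read-start models."""

import numpy as np
import pandas as pd
import pytest

from shallowcna import (
    BiasModel,
    CNAInterval,
    GenomeModel,
    SimulationConfig,
    count_starts,
    expected_duplicate_fraction,
    loucy_truth_set,
    read_count_variance,
    simulate_read_starts,
    simulate_window_counts,
    truth_cn_per_window,
)


class TestLoucyTruthSet:
    def test_six_events_five_losses_one_gain(self, hg19):
        truth = loucy_truth_set(hg19)
        assert len(truth) == 6
        directions = [iv.direction for iv in truth]
        assert directions.count("loss") == 5
        assert directions.count("gain") == 1
        gains = [iv for iv in truth if iv.direction == "gain"]
        assert gains[0].chrom == "chr13"

    def test_event_sizes(self, hg19):
        truth = loucy_truth_set(hg19)
        by_chrom = {}
        for iv in truth:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        # distal 5q deletion is ~72 Mb, 6q ~45 Mb, X is the whole chromosome
        assert by_chrom["chr5"][0].size == pytest.approx(72e6, rel=0.02)
        assert by_chrom["chr6"][0].size == pytest.approx(45e6, rel=0.02)
        assert by_chrom["chrX"][0].size == hg19.length("chrX")
        sizes_16 = sorted(iv.size for iv in by_chrom["chr16"])
        assert sizes_16[0] == pytest.approx(3e6, rel=0.15)
        assert sizes_16[1] == pytest.approx(13e6, rel=0.02)
        assert by_chrom["chr13"][0].size == pytest.approx(3e6, rel=0.02)

    def test_missing_chromosome_rejected(self):
        g = GenomeModel((("chr5", 180_915_260), ("chrX", 155_270_560)))
        with pytest.raises(ValueError, match="chr13|chr16|chr6"):
            loucy_truth_set(g)


class TestTruthRasterization:
    def test_no_events_diploid_autosomes(self, toy_genome):
        cn = truth_cn_per_window(toy_genome, [], 1_000_000)
        assert np.all(cn == 2.0)

    def test_aligned_gain_exact_windows(self, toy_genome):
        truth = [CNAInterval("chrA", 10_000_000, 13_000_000, "gain")]
        cn = truth_cn_per_window(toy_genome, truth, 1_000_000)
        assert np.all(cn[10:13] == 3.0)
        assert np.sum(cn == 3.0) == 3

    def test_half_window_loss_weighted_mean(self, toy_genome):
        truth = [CNAInterval("chrA", 10_500_000, 11_000_000, "loss")]
        cn = truth_cn_per_window(toy_genome, truth, 1_000_000)
        assert cn[10] == pytest.approx(1.5)

    def test_female_chrY_zero(self, hg19):
        cn = truth_cn_per_window(hg19, [], 1_000_000, sex="XX")
        from shallowcna import make_windows

        w = make_windows(hg19, 1_000_000)
        assert np.all(cn[(w["chrom"] == "chrY").to_numpy()] == 0.0)
        assert np.all(cn[(w["chrom"] == "chrX").to_numpy()] == 2.0)

    def test_conflicting_overlaps_rejected(self, toy_genome):
        truth = [
            CNAInterval("chrA", 0, 2_000_000, "gain"),
            CNAInterval("chrA", 1_000_000, 3_000_000, "loss"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            truth_cn_per_window(toy_genome, truth, 1_000_000)

    def test_explicit_copy_number_overrides_default(self, toy_genome):
        truth = [CNAInterval("chrA", 0, 1_000_000, "gain", copy_number=5.0)]
        cn = truth_cn_per_window(toy_genome, truth, 1_000_000)
        assert cn[0] == pytest.approx(5.0)


class TestWindowCounts:
    def test_unbiased_mean_matches_closed_form(self):
        # depth 0.8, 75 bp reads, 1 Mb windows -> lambda = 0.8e6 / 75 = 10666.7
        g = GenomeModel((("chr1", 500_000_000),))
        cfg = SimulationConfig(genome=g, seed=1)
        prof = simulate_window_counts(cfg)
        lam = 0.8 * 1e6 / 75
        mean = prof.df["raw_count"].mean()
        se = np.sqrt(lam / len(prof.df))
        assert abs(mean - lam) < 3 * se

    def test_zero_depth_all_zero(self, toy_genome):
        cfg = SimulationConfig(genome=toy_genome, mean_depth=0.0, seed=3)
        prof = simulate_window_counts(cfg)
        assert (prof.df["raw_count"] == 0).all()

    def test_seed_determinism_byte_identical(self, toy_genome):
        cfg = SimulationConfig(genome=toy_genome, seed=99, bias=BiasModel("lognormal", sigma=0.3))
        a = simulate_window_counts(cfg)
        b = simulate_window_counts(cfg)
        assert a.df.to_csv() == b.df.to_csv()

    def test_hotspot_regime_has_both_tails(self):
        g = GenomeModel((("chr1", 500_000_000),))
        bias = BiasModel("hotspot", sigma=0.3, hotspot_rate=40, hotspot_gain=1.0,
                         dropout_prob=0.2, dropout_factor=0.02)
        cfg = SimulationConfig(genome=g, seed=11, bias=bias)
        prof = simulate_window_counts(cfg)
        counts = prof.df["raw_count"].to_numpy(dtype=float)
        cn = 2 * counts / np.median(counts)
        assert (cn > 10).any(), "hotspot regime should produce extreme-CN outlier windows"
        assert (cn < 0.2).any(), "dropout should produce near-empty windows"

    def test_count_conservation_monte_carlo(self, toy_genome):
        # expected total = depth * G / read_length * (mean CN / 2)
        cfg = SimulationConfig(genome=toy_genome, seed=5)
        prof = simulate_window_counts(cfg)
        expected = 0.8 * toy_genome.total_length / 75
        total = prof.df["raw_count"].sum()
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_gc_bias_visible_in_counts(self):
        g = GenomeModel((("chr1", 300_000_000),))
        bias = BiasModel(gc_bias_coeffs=(0.2, 0.0, 5.0))
        prof = simulate_window_counts(SimulationConfig(genome=g, seed=21, bias=bias))
        r = np.corrcoef(prof.df["raw_count"], prof.df["gc"])[0, 1]
        assert abs(r) > 0.3

    def test_variance_statistic_increases_with_sigma(self):
        """More lognormal bias -> larger Poisson-corrected variance, 20 reps per level."""
        g = GenomeModel((("chr1", 300_000_000),))
        means = []
        for sigma in (0.0, 0.15, 0.4):
            kind = "none" if sigma == 0 else "lognormal"
            stats = []
            for rep in range(20):
                cfg = SimulationConfig(genome=g, seed=1000 + rep, bias=BiasModel(kind, sigma=sigma))
                prof = simulate_window_counts(cfg)
                stats.append(read_count_variance(prof.df["raw_count"].to_numpy()).statistic)
            means.append(np.mean(stats))
        assert means[0] < means[1] < means[2]


class TestReadStarts:
    def test_single_read(self, toy_genome):
        df = simulate_read_starts(1, toy_genome, seed=0)
        assert len(df) == 1
        assert df.iloc[0]["chrom"] in toy_genome.names
        assert df.iloc[0]["strand"] in "+-"

    def test_memory_guard(self, toy_genome):
        with pytest.raises(ValueError, match="memory guard"):
            simulate_read_starts(10**7, toy_genome, max_reads=10**6)

    def test_seed_determinism(self, toy_genome):
        a = simulate_read_starts(10_000, toy_genome, seed=4)
        b = simulate_read_starts(10_000, toy_genome, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_duplicate_fraction_matches_closed_form(self):
        """1e6 uniform starts on a 1e8 bp toy genome vs the collision formula."""
        g = GenomeModel((("chr1", 100_000_000),))
        n = 1_000_000
        df = simulate_read_starts(n, g, seed=7)
        key = df["pos"].to_numpy() * 2 + (df["strand"] == "-").to_numpy()
        _, counts = np.unique(key, return_counts=True)
        observed = counts[counts >= 2].sum() / n
        expected = expected_duplicate_fraction(n, 2 * g.total_length)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_hotspot_mass_builds_up_in_windows(self):
        """Half the reads packed into ~48 kb hotspots shows up as window pileups."""
        g = GenomeModel((("chr1", 100_000_000),))
        bias = BiasModel("hotspot", hotspot_rate=50, hotspot_gain=1.5)
        df = simulate_read_starts(200_000, g, bias=bias, seed=9, hotspot_fraction=0.5)
        prof = count_starts(df, g, 1_000_000)
        counts = prof.df["raw_count"].to_numpy()
        # uniform expectation is 1000/window +- ~32; pileup windows dwarf that
        assert counts.max() > 5 * 200_000 / 100
        assert len(df) == counts.sum()


class TestConfigSerialization:
    def test_yaml_round_trip(self, tmp_path, toy_genome):
        cfg = SimulationConfig(
            genome=toy_genome,
            truth=(CNAInterval("chrA", 0, 2_000_000, "loss"),),
            seed=42,
            bias=BiasModel("hotspot", sigma=0.2, dropout_prob=0.1, gc_bias_coeffs=(1.0, 0.5, -0.2)),
        )
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg

    def test_invalid_config_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            SimulationConfig(genome=toy_genome, window_size=0)
        with pytest.raises(ValueError):
            BiasModel(sigma=-1)
        with pytest.raises(ValueError):
            BiasModel(dropout_prob=1.5)
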