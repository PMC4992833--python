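"""Window grids, start counting, blacklist masking and normalization."""

import numpy as np
import pandas as pd
import pytest

from shallowcna import (
    BiasModel,
    CNAInterval,
    GenomeModel,
    SimulationConfig,
    apply_blacklist,
    correct_gc_mappability,
    count_starts,
    loucy_truth_set,
    make_windows,
    median_normalize,
    normalize_profile,
    simulate_window_counts,
    truth_cn_per_window,
)


class TestMakeWindows:
    def test_exact_tiling(self):
        g = GenomeModel((("c", 10_000_000),))
        w = make_windows(g, 1_000_000)
        assert len(w) == 10
        assert (w["end"] - w["start"] == 1_000_000).all()

    def test_short_last_window(self):
        g = GenomeModel((("c", 10_500_000),))
        w = make_windows(g, 1_000_000)
        assert len(w) == 11
        assert w.iloc[-1]["end"] - w.iloc[-1]["start"] == 500_000

    def test_hg19_window_total(self, hg19):
        """Window count equals the per-chromosome ceiling sum (~3100 at 1 Mb)."""
        w = make_windows(hg19, 1_000_000)
        expected = sum(-(-length // 1_000_000) for _, length in hg19.chromosomes)
        assert len(w) == expected
        assert 3_050 <= expected <= 3_150

    def test_window_size_validation(self, toy_genome):
        with pytest.raises(ValueError):
            make_windows(toy_genome, 0)
        with pytest.warns(UserWarning):
            make_windows(toy_genome, 10**9)


class TestCountStarts:
    def test_zero_reads(self, toy_genome):
        prof = count_starts(pd.DataFrame({"chrom": [], "pos": []}), toy_genome)
        assert (prof.df["raw_count"] == 0).all()

    def test_half_open_boundary(self):
        g = GenomeModel((("c", 3_000_000),))
        reads = pd.DataFrame({"chrom": ["c", "c"], "pos": [999_999, 1_000_000]})
        prof = count_starts(reads, g, 1_000_000)
        assert prof.df["raw_count"].tolist() == [1, 1, 0]

    def test_unknown_chromosome_rejected(self, toy_genome):
        reads = pd.DataFrame({"chrom": ["chrZ"], "pos": [5]})
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_starts(reads, toy_genome)

    def test_out_of_bounds_rejected(self, toy_genome):
        reads = pd.DataFrame({"chrom": ["chrA"], "pos": [toy_genome.length("chrA")]})
        with pytest.raises(ValueError, match="out of bounds"):
            count_starts(reads, toy_genome)

    def test_matches_brute_force_tally(self, toy_genome, rng):
        """1e5 random reads: vectorized counting equals a dict-based tally."""
        n = 100_000
        chroms = rng.choice(toy_genome.names, n, p=[5 / 8, 3 / 8])
        pos = np.array(
            [rng.integers(0, toy_genome.length(c)) for c in chroms], dtype=np.int64
        )
        reads = pd.DataFrame({"chrom": chroms, "pos": pos})
        prof = count_starts(reads, toy_genome, 1_000_000)

        tally: dict[tuple[str, int], int] = {}
        for c, p in zip(chroms, pos):
            key = (c, int(p) // 1_000_000)
            tally[key] = tally.get(key, 0) + 1
        for _, row in prof.df.iterrows():
            expected = tally.get((row["chrom"], row["start"] // 1_000_000), 0)
            assert row["raw_count"] == expected
        assert prof.df["raw_count"].sum() == n


class TestBlacklist:
    def _profile(self, genome):
        cfg = SimulationConfig(genome=genome, seed=0)
        return simulate_window_counts(cfg)

    def test_empty_blacklist_flags_nothing(self, toy_genome):
        prof = apply_blacklist(self._profile(toy_genome), [])
        assert not prof.df["blacklisted"].any()

    def test_whole_window_flagged(self, toy_genome):
        bl = [CNAInterval("chrA", 3_000_000, 4_000_000, "loss")]
        prof = apply_blacklist(self._profile(toy_genome), bl)
        flagged = prof.df.loc[prof.df["blacklisted"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["start"] == 3_000_000

    def test_overlap_threshold_semantics(self, toy_genome):
        # 40% overlap with min_overlap_frac 0.5 -> not flagged; 50% -> flagged
        bl = [CNAInterval("chrA", 3_000_000, 3_400_000, "loss")]
        prof = apply_blacklist(self._profile(toy_genome), bl, min_overlap_frac=0.5)
        assert not prof.df["blacklisted"].any()
        bl = [CNAInterval("chrA", 3_000_000, 3_500_000, "loss")]
        prof = apply_blacklist(self._profile(toy_genome), bl, min_overlap_frac=0.5)
        assert prof.df["blacklisted"].sum() == 1

    def test_low_mappability_flagged(self, toy_genome):
        prof = self._profile(toy_genome)
        prof.df.loc[2, "mappability"] = 0.1
        out = apply_blacklist(prof, [])
        assert out.df.loc[2, "blacklisted"]


class TestGCCorrection:
    def test_constant_annotations_identity(self, toy_genome):
        prof = simulate_window_counts(SimulationConfig(genome=toy_genome, seed=2))
        prof.df["gc"] = 0.41
        prof.df["mappability"] = 0.95
        out = correct_gc_mappability(prof)
        # no signal to remove: corrected equals (width-adjusted) raw
        full = out.df["end"] - out.df["start"] == 1_000_000
        assert np.allclose(
            out.df.loc[full, "corrected_count"], out.df.loc[full, "raw_count"]
        )

    def test_all_equal_counts_stay_equal(self, toy_genome):
        prof = simulate_window_counts(SimulationConfig(genome=toy_genome, seed=2))
        prof.df["raw_count"] = 500
        out = correct_gc_mappability(prof)
        full = out.df["end"] - out.df["start"] == 1_000_000
        vals = out.df.loc[full, "corrected_count"].to_numpy()
        assert np.allclose(vals, vals[0], rtol=0.02)

    def test_quadratic_gc_bias_recovered(self):
        """Simulated GC bias is attenuated below |r| = 0.1 after correction."""
        g = GenomeModel((("chr1", 300_000_000),))
        bias = BiasModel(gc_bias_coeffs=(0.2, 0.0, 5.0))
        prof = simulate_window_counts(SimulationConfig(genome=g, seed=13, bias=bias))
        before = np.corrcoef(prof.df["raw_count"], prof.df["gc"])[0, 1]
        out = correct_gc_mappability(prof)
        after = np.corrcoef(out.df["corrected_count"], out.df["gc"])[0, 1]
        assert abs(before) > 0.3
        assert abs(after) < 0.1


class TestMedianNormalize:
    def _flat_profile(self, counts):
        g = GenomeModel((("c", len(counts) * 1_000_000),))
        prof = simulate_window_counts(SimulationConfig(genome=g, seed=0))
        prof.df["raw_count"] = counts
        return prof

    def test_formula_identities(self):
        prof = median_normalize(self._flat_profile([100] * 20 + [150, 0]))
        cn = prof.df["cn"].to_numpy()
        assert cn[0] == pytest.approx(2.0)  # count == median
        assert cn[20] == pytest.approx(3.0)  # 1.5x median
        assert cn[21] == pytest.approx(0.0)  # zero count

    def test_median_cn_is_two_exactly(self, toy_genome):
        prof = simulate_window_counts(SimulationConfig(genome=toy_genome, seed=8))
        out = median_normalize(correct_gc_mappability(prof))
        assert np.nanmedian(out.df["cn"][out.usable]) == pytest.approx(2.0, abs=1e-12)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="median|usable"):
            median_normalize(self._flat_profile([0] * 10))

    def test_uniform_scaling_invariance(self, toy_genome):
        prof = simulate_window_counts(SimulationConfig(genome=toy_genome, seed=9))
        a = normalize_profile(prof.copy())
        scaled = prof.copy()
        scaled.df["raw_count"] *= 7
        b = normalize_profile(scaled)
        assert np.allclose(a.df["cn"], b.df["cn"], equal_nan=True)


class TestEndToEndCN:
    def test_loucy_window_cn_recovery(self, hg19_female):
        """Across replicates, loss windows average near CN 1 and gain windows near 3."""
        truth = loucy_truth_set(hg19_female)
        truth_cn = truth_cn_per_window(hg19_female, truth, 1_000_000)
        loss_w = truth_cn == 1.0
        gain_w = truth_cn == 3.0
        loss_means, gain_means = [], []
        for rep in range(20):
            cfg = SimulationConfig(genome=hg19_female, truth=tuple(truth), seed=7000 + rep)
            prof = normalize_profile(simulate_window_counts(cfg))
            cn = prof.df["cn"].to_numpy()
            loss_means.append(np.nanmean(cn[loss_w]))
            gain_means.append(np.nanmean(cn[gain_w]))
        assert 0.9 <= np.mean(loss_means) <= 1.1
        assert 2.8 <= np.mean(gain_means) <= 3.2
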