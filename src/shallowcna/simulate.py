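"""Synthetic shallow-sequencing data with known truth CNAs and
configurable whole-genome-amplification representation bias.

The generator stands in for sequencing runs of amplified few-cell DNA.
Per-window read counts are Poisson around a rate proportional to local
copy number and depth; a multiplicative per-window bias factor models
WGA representation bias, from none (unamplified-like), through mild
mean-one lognormal scatter (a well-behaved amplification), up to a
hotspot/dropout regime in which a Pareto-tailed minority of windows
soaks up reads (normalized CN far above 2) while others drop toward
zero — the pattern seen when amplification priming concentrates on a
few loci.  A read-start-level generator supports dereplication studies.

Default study conditions: 1 Mb windows, mean depth 0.8x, 75 bp
single-end reads, a diploid female baseline (chrY excluded), and a
bundled six-event truth set for the LOUCY leukemia cell line (five
deletions and one ~3 Mb duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .binning import BinnedProfile, make_windows
from .genome import CNAInterval, GenomeModel, ReadStartRecord

__all__ = [
    "BiasModel",
    "SimulationConfig",
    "loucy_truth_set",
    "truth_cn_per_window",
    "simulate_window_counts",
    "simulate_read_starts",
    "read_starts_to_frame",
]

MEAN_GC = 0.41  # centre of the simulated window GC distribution


@dataclass(frozen=True)
class BiasModel:
    """Multiplicative per-window representation-bias model.

    kind="none"      b_i = 1 everywhere (unamplified-like uniformity).
    kind="lognormal" b_i = exp(sigma * Z - sigma^2 / 2): mean-one
                     lognormal scatter, so depth and bias stay
                     orthogonal knobs.
    kind="hotspot"   on top of the lognormal scatter, over-amplified
                     regions seeded by a Poisson process at
                     ``hotspot_rate`` per Gb get a Pareto
                     (shape=hotspot_gain) amplification factor, and a
                     ``dropout_prob`` fraction of windows falls in
                     under-amplified regions multiplied by
                     ``dropout_factor``, producing both extreme-CN
                     outliers and read deserts.  Both kinds of region
                     extend over a geometric number of consecutive
                     windows (mean ``span_windows``), emulating the
                     multi-window over-/under-represented stretches
                     seen in heavily biased amplifications.

    ``gc_bias_coeffs`` (c0, c1, c2) optionally adds a quadratic GC
    response c0 + c1*gc + c2*gc^2 (mean-normalized), giving the
    normalization stage a recoverable signal.
    """

    kind: Literal["none", "lognormal", "hotspot"] = "none"
    sigma: float = 0.0
    hotspot_rate: float = 10.0  # expected hotspot regions per Gb
    hotspot_gain: float = 1.0  # Pareto tail shape (smaller = heavier)
    dropout_prob: float = 0.0
    dropout_factor: float = 0.05
    span_windows: float = 3.0  # mean length of a biased region, in windows
    gc_bias_coeffs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if not 0 < self.dropout_factor <= 1:
            raise ValueError("dropout_factor must be in (0, 1]")
        if self.span_windows < 1:
            raise ValueError("span_windows must be >= 1")

    def _region_runs(
        self, n: int, n_regions: int, rng: np.random.Generator
    ) -> list[tuple[int, int]]:
        """Random region starts with geometric run lengths (mean span_windows)."""
        runs = []
        if n_regions <= 0:
            return runs
        starts = rng.integers(0, n, n_regions)
        p = 1.0 / self.span_windows
        lengths = rng.geometric(p, n_regions)
        for s, l in zip(starts, lengths):
            runs.append((int(s), int(min(n, s + l))))
        return runs

    def window_factors(
        self, n: int, rng: np.random.Generator, window_size: int = 1_000_000
    ) -> np.ndarray:
        """Draw the per-window bias factors b_i."""
        b = np.ones(n)
        if self.kind in ("lognormal", "hotspot") and self.sigma > 0:
            b *= np.exp(self.sigma * rng.standard_normal(n) - self.sigma**2 / 2)
        if self.kind == "hotspot":
            span_bp = n * window_size
            n_hot = rng.poisson(self.hotspot_rate * span_bp * 1e-9)
            for s, e in self._region_runs(n, n_hot, rng):
                b[s:e] *= 1.0 + rng.pareto(self.hotspot_gain) * 10.0
            n_drop = rng.poisson(self.dropout_prob * n / self.span_windows)
            for s, e in self._region_runs(n, n_drop, rng):
                b[s:e] *= self.dropout_factor
        return b

    def gc_response(self, gc: np.ndarray) -> np.ndarray:
        """Mean-normalized quadratic GC response g(gc)."""
        if self.gc_bias_coeffs is None:
            return np.ones_like(gc)
        c0, c1, c2 = self.gc_bias_coeffs
        g = c0 + c1 * gc + c2 * gc**2
        g = np.clip(g, 1e-6, None)
        return g / g.mean()


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic sample; a fixed seed reproduces it exactly."""

    genome: GenomeModel
    truth: tuple[CNAInterval, ...] = ()
    window_size: int = 1_000_000
    mean_depth: float = 0.8
    read_length: int = 75
    seed: int = 0
    bias: BiasModel = field(default_factory=BiasModel)
    ploidy_baseline: int = 2
    sex: Literal["XX", "XY"] = "XX"

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "genome": [list(c) for c in self.genome.chromosomes],
            "truth": [
                [iv.chrom, iv.start, iv.end, iv.direction, iv.copy_number]
                for iv in self.truth
            ],
            "window_size": self.window_size,
            "mean_depth": self.mean_depth,
            "read_length": self.read_length,
            "seed": self.seed,
            "bias": asdict(self.bias),
            "ploidy_baseline": self.ploidy_baseline,
            "sex": self.sex,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bias = d.get("bias", {})
        if bias.get("gc_bias_coeffs") is not None:
            bias["gc_bias_coeffs"] = tuple(bias["gc_bias_coeffs"])
        return cls(
            genome=GenomeModel(tuple((c, int(l)) for c, l in d["genome"])),
            truth=tuple(
                CNAInterval(c, int(s), int(e), dr, cn)
                for c, s, e, dr, cn in d.get("truth", [])
            ),
            window_size=int(d["window_size"]),
            mean_depth=float(d["mean_depth"]),
            read_length=int(d["read_length"]),
            seed=int(d["seed"]),
            bias=BiasModel(**bias),
            ploidy_baseline=int(d.get("ploidy_baseline", 2)),
            sex=d.get("sex", "XX"),
        )


# Truth CNAs of the LOUCY cell line as characterized by high-resolution
# arrayCGH: whole-X loss, two large distal 5q/6q deletions, a small 13q
# duplication and two 16p/16q deletions.  The cytobands give only
# approximate positions, so the exact coordinates are fixed package
# constants; interior boundaries sit on 1 Mb multiples so the events
# are representable at the method's default window grid, and distal
# events run to the chromosome end.
_LOUCY_EVENTS: tuple[tuple[str, int, int | None, str], ...] = (
    # (chrom, start, end or None = chromosome end, direction)
    ("chr5", 109_000_000, None, "loss"),  # distal 5q21.3-q35.3, ~72 Mb
    ("chr6", 126_000_000, None, "loss"),  # distal 6q22.31-q27, ~45 Mb
    ("chr13", 103_000_000, 106_000_000, "gain"),  # 13q33-q33.3 duplication, ~3 Mb
    ("chr16", 0, 13_000_000, "loss"),  # 16p13.3-p13.12, ~13 Mb
    ("chr16", 87_000_000, None, "loss"),  # distal 16q24.2-q24.3, ~3.4 Mb
    ("chrX", 0, None, "loss"),  # whole-chromosome X loss
)


def loucy_truth_set(genome: GenomeModel) -> list[CNAInterval]:
    """The six reference CNAs of the LOUCY cell line on ``genome``.

    Five deletions (whole chrX, distal 5q and 6q, 16p and distal 16q)
    plus one ~3 Mb duplication on 13q.  Distal events are anchored to
    the chromosome end so they stay consistent with the supplied
    chromosome lengths.
    """
    required = {"chr5", "chr6", "chr13", "chr16", "chrX"}
    missing = required - set(genome.names)
    if missing:
        raise ValueError(f"genome lacks required chromosome(s): {sorted(missing)}")
    out = []
    for chrom, start, end, direction in _LOUCY_EVENTS:
        if end is None:
            end = genome.length(chrom)
        out.append(CNAInterval(chrom, start, end, direction))  # type: ignore[arg-type]
    out.sort(key=lambda iv: (genome.order(iv.chrom), iv.start))
    return out


def truth_cn_per_window(
    genome: GenomeModel,
    truth: Sequence[CNAInterval],
    window_size: int,
    sex: Literal["XX", "XY"] = "XX",
    ploidy_baseline: int = 2,
) -> np.ndarray:
    """Rasterize truth CNAs onto the window grid as real-valued CN.

    Baseline CN is the diploid 2 on autosomes; for an XY genome chrX and
    chrY are haploid (CN 1), for XX chrX is 2 and chrY 0.  A loss sets
    CN to baseline - 1 (or the event's explicit ``copy_number``), a gain
    to baseline + 1; windows partially covered take the length-weighted
    mean of inside/outside CN.  Overlapping events with conflicting
    directions are rejected.
    """
    windows = make_windows(genome, window_size)
    chrom_arr = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_end = windows["end"].to_numpy()
    width = (w_end - w_start).astype(np.float64)

    base = np.full(len(windows), float(ploidy_baseline))
    if sex == "XX":
        base[chrom_arr == "chrY"] = 0.0
    else:
        base[chrom_arr == "chrX"] = ploidy_baseline / 2.0
        base[chrom_arr == "chrY"] = ploidy_baseline / 2.0

    for a in truth:
        for b in truth:
            if a is not b and a.overlap(b) > 0 and a.direction != b.direction:
                raise ValueError(
                    f"conflicting overlapping truth events on {a.chrom}: "
                    f"{a.start}-{a.end} ({a.direction}) vs {b.start}-{b.end} ({b.direction})"
                )

    delta = np.zeros(len(windows))  # length-weighted CN shift per window
    for iv in truth:
        sel = chrom_arr == iv.chrom
        if not sel.any():
            continue
        ov = np.clip(
            np.minimum(w_end[sel], iv.end) - np.maximum(w_start[sel], iv.start), 0, None
        ).astype(np.float64)
        if iv.copy_number is not None:
            event_cn = float(iv.copy_number)
        else:
            event_cn = ploidy_baseline + (1 if iv.direction == "gain" else -1)
        shift = event_cn - base[sel]
        delta[sel] += shift * ov / width[sel]
    return np.maximum(base + delta, 0.0)


def simulate_window_counts(config: SimulationConfig) -> BinnedProfile:
    """One synthetic sample as per-window raw counts with annotations.

    count_i ~ Poisson(lambda_i) with

        lambda_i = (mean_depth * width_i / read_length)
                   * (CN_i / 2) * b_i * g(gc_i)

    where b_i comes from the bias model and g is the (optional) GC
    response.  Window GC is drawn from a truncated bell around 0.41 and
    mappability from a tight high band; both are recorded so the
    normalization stage can be exercised against a recoverable signal.
    """
    rng = np.random.default_rng(config.seed)
    windows = make_windows(config.genome, config.window_size)
    n = len(windows)
    if n == 0:
        raise ValueError("empty genome")
    width = (windows["end"] - windows["start"]).to_numpy(dtype=np.float64)

    cn = truth_cn_per_window(
        config.genome, config.truth, config.window_size, config.sex, config.ploidy_baseline
    )

    # annotations: GC ~ truncated normal around 0.41, mappability high
    gc = np.clip(rng.normal(MEAN_GC, 0.05, n), 0.25, 0.65)
    mappability = np.clip(rng.normal(0.95, 0.02, n), 0.5, 1.0)

    b = config.bias.window_factors(n, rng, config.window_size)
    g = config.bias.gc_response(gc)
    lam = (config.mean_depth * width / config.read_length) * (cn / 2.0) * b * g
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite Poisson rate (lambda overflow)")
    counts = rng.poisson(lam)

    df = windows.copy()
    df["raw_count"] = counts.astype(np.int64)
    df["gc"] = gc
    df["mappability"] = mappability
    df["blacklisted"] = False
    return BinnedProfile(genome=config.genome, window_size=config.window_size, df=df)


def simulate_read_starts(
    n_reads: int,
    genome: GenomeModel,
    bias: BiasModel | None = None,
    seed: int = 0,
    hotspot_fraction: float = 0.5,
    hotspot_width: int = 48_000,
    max_reads: int = 100_000_000,
) -> pd.DataFrame:
    """Simulate mapped read-start records (chrom, pos, strand).

    With no bias, starts are uniform over the 2 * genome_length
    (position, strand) sites.  Under a hotspot bias,
    ``hotspot_fraction`` of the reads is instead concentrated in short
    hotspot regions (one ~48 kb region per hotspot, matching the
    buildup length scale seen in heavily biased amplifications), the
    rest staying uniform.  Returns a DataFrame sorted by nothing (reads
    arrive in generation order) with columns chrom, pos, strand.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if n_reads > max_reads:
        raise ValueError(f"n_reads={n_reads} exceeds memory guard max_reads={max_reads}")
    bias = bias or BiasModel()
    rng = np.random.default_rng(seed)
    G = genome.total_length

    lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    bounds = np.concatenate([[0], np.cumsum(lengths)])

    n_hot = 0
    if bias.kind == "hotspot" and hotspot_fraction > 0:
        expected = max(1, int(round(bias.hotspot_rate * G / 1e9)))
        n_hot = max(1, int(rng.poisson(expected)))
        hot_starts = rng.integers(0, G - hotspot_width, n_hot)
        weights = 1.0 + rng.pareto(bias.hotspot_gain, n_hot)
        weights /= weights.sum()
        n_in_hot = int(rng.binomial(n_reads, hotspot_fraction))
    else:
        n_in_hot = 0

    flat = np.empty(n_reads, dtype=np.int64)
    n_uniform = n_reads - n_in_hot
    flat[:n_uniform] = rng.integers(0, G, n_uniform)
    if n_in_hot:
        which = rng.choice(n_hot, n_in_hot, p=weights)
        flat[n_uniform:] = hot_starts[which] + rng.integers(0, hotspot_width, n_in_hot)
    strand = np.where(rng.random(n_reads) < 0.5, "+", "-")

    chrom_idx = np.searchsorted(bounds, flat, side="right") - 1
    pos = flat - bounds[chrom_idx]
    names = np.array(genome.names, dtype=object)
    return pd.DataFrame({"chrom": names[chrom_idx], "pos": pos, "strand": strand})


def read_starts_to_frame(reads: Sequence[ReadStartRecord]) -> pd.DataFrame:
    """Convert record objects to the tabular form the binning stage takes."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "pos": [r.pos for r in reads],
            "strand": [r.strand for r in reads],
        }
    )
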