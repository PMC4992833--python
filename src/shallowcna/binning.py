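"""Fixed-size window binning and copy-number normalization.

Read starts are counted in non-overlapping fixed-size windows tiling
each chromosome (1 Mb by default, giving a ~3 Mb calling resolution),
blacklisted regions are masked out, counts are corrected for GC content
and mappability, and copy number is estimated by median normalization:

    CN_i = 2 * corrected_count_i / median(corrected counts)

which assumes aberrations are rare enough that the genome-wide median
window reflects the diploid state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CNAInterval, GenomeModel, ReadStartRecord

__all__ = [
    "BinnedProfile",
    "make_windows",
    "count_starts",
    "apply_blacklist",
    "correct_gc_mappability",
    "median_normalize",
    "normalize_profile",
]

DEFAULT_WINDOW_SIZE = 1_000_000
MIN_MAPPABILITY = 0.2  # windows below this are treated as blacklisted


@dataclass
class BinnedProfile:
    """Per-window read counts with annotations and derived CN estimates.

    ``df`` has one row per window in genome order with columns
    ``chrom, start, end, raw_count, gc, mappability, blacklisted`` and,
    once the normalization stages have run, ``corrected_count`` and
    ``cn``.  Blacklisted windows keep their raw counts but carry NaN in
    the derived columns and are excluded from every downstream statistic.
    """

    genome: GenomeModel
    window_size: int
    df: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return len(self.df)

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of windows entering statistics."""
        return ~self.df["blacklisted"].to_numpy()

    def copy(self) -> "BinnedProfile":
        return replace(self, df=self.df.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, genome: GenomeModel, window_size: int
    ) -> "BinnedProfile":
        df = pd.read_csv(path, sep="\t")
        df["blacklisted"] = df["blacklisted"].astype(bool)
        return cls(genome=genome, window_size=window_size, df=df)


def make_windows(genome: GenomeModel, window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Tile each chromosome with fixed-size windows, concatenated in genome order.

    Each chromosome contributes ceil(length / window_size) windows; the
    last one may be short.  Window order is a pure function of the
    genome model, so the same genome always yields the same indexing.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if window_size > max(l for _, l in genome.chromosomes):
        import warnings

        warnings.warn(
            "window_size exceeds the longest chromosome; every chromosome "
            "collapses to a single window",
            stacklevel=2,
        )
    rows = []
    for name, length in genome.chromosomes:
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _chrom_offsets(genome: GenomeModel, window_size: int) -> dict[str, int]:
    """First window index of each chromosome in the concatenated grid."""
    offsets: dict[str, int] = {}
    acc = 0
    for name, length in genome.chromosomes:
        offsets[name] = acc
        acc += -(-length // window_size)
    return offsets


def count_starts(
    reads: Sequence[ReadStartRecord] | pd.DataFrame,
    genome: GenomeModel,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> BinnedProfile:
    """Count read starts per window; every read lands in exactly one window.

    ``reads`` is either a sequence of :class:`ReadStartRecord` or a
    DataFrame with ``chrom``/``pos`` columns.  Window membership is by
    start position only (half-open windows), so the total of the counts
    equals the number of reads.
    """
    windows = make_windows(genome, window_size)
    offsets = _chrom_offsets(genome, window_size)

    if isinstance(reads, pd.DataFrame):
        chroms = reads["chrom"].to_numpy()
        pos = reads["pos"].to_numpy(dtype=np.int64)
    else:
        chroms = np.array([r.chrom for r in reads], dtype=object)
        pos = np.array([r.pos for r in reads], dtype=np.int64)

    counts = np.zeros(len(windows), dtype=np.int64)
    if len(pos):
        unknown = set(np.unique(chroms)) - set(genome.names)
        if unknown:
            raise ValueError(f"reads on unknown chromosome(s): {sorted(unknown)}")
        for name, length in genome.chromosomes:
            sel = chroms == name
            if not sel.any():
                continue
            p = pos[sel]
            if (p < 0).any() or (p >= length).any():
                raise ValueError(f"read position out of bounds on {name}")
            idx = offsets[name] + p // window_size
            counts += np.bincount(idx, minlength=len(windows))

    df = windows.copy()
    df["raw_count"] = counts
    df["gc"] = np.nan
    df["mappability"] = np.nan
    df["blacklisted"] = False
    return BinnedProfile(genome=genome, window_size=window_size, df=df)


def apply_blacklist(
    profile: BinnedProfile,
    blacklist: Sequence[CNAInterval],
    min_overlap_frac: float = 0.5,
) -> BinnedProfile:
    """Flag windows whose blacklist overlap fraction reaches ``min_overlap_frac``.

    Flagged windows are excluded from all downstream statistics (median,
    segmentation, variance).  Windows with mappability below
    ``MIN_MAPPABILITY`` are flagged as well, mirroring the exclusion of
    poorly mappable regions from count-based analysis.
    """
    out = profile.copy()
    df = out.df
    overlap = np.zeros(len(df), dtype=np.float64)
    for iv in blacklist:
        sel = df["chrom"] == iv.chrom
        if not sel.any():
            continue
        s = df.loc[sel, "start"].to_numpy()
        e = df.loc[sel, "end"].to_numpy()
        ov = np.clip(np.minimum(e, iv.end) - np.maximum(s, iv.start), 0, None)
        overlap[sel.to_numpy()] += ov
    width = (df["end"] - df["start"]).to_numpy()
    frac = overlap / width
    flagged = frac >= min_overlap_frac
    mapp = df["mappability"].to_numpy()
    low_mapp = np.isfinite(mapp) & (mapp < MIN_MAPPABILITY)
    df["blacklisted"] = df["blacklisted"].to_numpy() | flagged | low_mapp
    for col in ("corrected_count", "cn"):
        if col in df.columns:
            df.loc[df["blacklisted"], col] = np.nan
    return out


def _width_adjusted(df: pd.DataFrame, window_size: int) -> np.ndarray:
    """Raw counts rescaled to full-window equivalents.

    The terminal window of a chromosome is usually shorter than the
    nominal window size and collects proportionally fewer reads; left
    unadjusted it masquerades as a deletion, so counts are scaled by
    window_size / width before any normalization.
    """
    raw = df["raw_count"].to_numpy(dtype=np.float64)
    width = (df["end"] - df["start"]).to_numpy(dtype=np.float64)
    return raw * (window_size / width)


def correct_gc_mappability(profile: BinnedProfile, trim_frac: float = 0.01) -> BinnedProfile:
    """Remove GC-content and mappability bias from raw window counts.

    Counts are first rescaled to full-window equivalents (short
    terminal windows), then a quadratic response surface in
    (gc, mappability) is least-squares fitted to the usable counts —
    after trimming the most extreme ``trim_frac`` tails of the count
    distribution so amplification outliers do not steer the fit — and
    each count is divided by the fitted relative response, rescaled so
    the mean correction factor over usable windows is 1.  With no
    GC/mappability signal the corrected counts equal the raw counts up
    to that rescaling.

    Windows lacking gc or mappability annotations fall back to
    corrected = width-adjusted raw.
    """
    out = profile.copy()
    df = out.df
    usable = out.usable
    raw = _width_adjusted(df, out.window_size)
    gc = df["gc"].to_numpy(dtype=np.float64)
    mapp = df["mappability"].to_numpy(dtype=np.float64)

    corrected = raw.astype(np.float64).copy()
    annotated = usable & np.isfinite(gc) & np.isfinite(mapp)
    n_fit = int(annotated.sum())
    if n_fit >= 12:  # minimum support for a 6-term surface
        y = raw[annotated]
        lo, hi = np.quantile(y, [trim_frac, 1 - trim_frac])
        keep = (y >= lo) & (y <= hi)
        if keep.sum() >= 12:
            g = gc[annotated][keep]
            m = mapp[annotated][keep]
            X = np.column_stack([np.ones(keep.sum()), g, g**2, m, m**2, g * m])
            coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
            Xall = np.column_stack(
                [np.ones(annotated.sum()), gc[annotated], gc[annotated] ** 2,
                 mapp[annotated], mapp[annotated] ** 2, gc[annotated] * mapp[annotated]]
            )
            fitted = Xall @ coef
            mean_fit = float(np.mean(fitted))
            # Guard against a degenerate fit (non-positive expected counts).
            if mean_fit > 0 and np.all(fitted > 0.05 * mean_fit):
                factor = fitted / mean_fit
                corrected[annotated] = raw[annotated] / factor
    df["corrected_count"] = np.where(usable, corrected, np.nan)
    return out


def median_normalize(profile: BinnedProfile) -> BinnedProfile:
    """Estimate per-window copy number: cn = 2 * corrected / median(corrected).

    The median is taken over all usable windows genome-wide.  Requires a
    positive median; an all-zero profile is degenerate and rejected.
    """
    out = profile.copy()
    df = out.df
    if "corrected_count" not in df.columns:
        df["corrected_count"] = np.where(
            out.usable, _width_adjusted(df, out.window_size), np.nan
        )
    usable = out.usable
    vals = df["corrected_count"].to_numpy(dtype=np.float64)[usable]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no usable windows to normalize")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("median corrected count is zero; degenerate profile")
    cn = 2.0 * df["corrected_count"].to_numpy(dtype=np.float64) / med
    df["cn"] = np.where(usable, cn, np.nan)
    return out


def normalize_profile(
    profile: BinnedProfile,
    blacklist: Sequence[CNAInterval] = (),
    min_overlap_frac: float = 0.5,
) -> BinnedProfile:
    """Blacklist -> GC/mappability correction -> median normalization."""
    p = apply_blacklist(profile, blacklist, min_overlap_frac)
    p = correct_gc_mappability(p)
    return median_normalize(p)
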