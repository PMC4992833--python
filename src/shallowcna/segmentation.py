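"""Circular binary segmentation (CBS) of window copy-number profiles and
threshold-based CNA calling.

Each chromosome's vector of usable-window CN estimates is treated as a
circle.  The arc maximizing the two-sample t-statistic between the
values inside and outside the arc is the candidate change-point pair;
it is accepted when its permutation p-value falls below ``alpha``, and
the algorithm recurses on the resulting pieces.  Segment copy number is
the mean of the member windows' CN (on the CN scale), and a segment is
called a gain when log2(mean_cn / 2) strictly exceeds the calling
threshold (+0.35 by default, i.e. CN > 2.55) and a loss when it falls
strictly below -0.35 (CN < 1.57).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .binning import BinnedProfile
from .genome import CNAInterval, GenomeModel

__all__ = [
    "Segment",
    "SegmentationParams",
    "max_t_arc",
    "cbs_segment",
    "segment_profile",
    "call_segments",
    "segments_to_calls",
    "plot_profile",
]

Call = Literal["gain", "loss", "neutral"]


@dataclass
class Segment:
    """A run of consecutive usable windows with a common copy number."""

    chrom: str
    first: int  # index of first member window (within the chromosome's usable windows)
    last: int  # inclusive
    start: int  # bp, inclusive
    end: int  # bp, exclusive
    mean_cn: float
    log2ratio: float = field(init=False)
    call: Call = "neutral"

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore"):
            self.log2ratio = float(np.log2(self.mean_cn / 2.0)) if self.mean_cn > 0 else -np.inf

    @property
    def n_windows(self) -> int:
        return self.last - self.first + 1


@dataclass
class SegmentationParams:
    """Tuning knobs for CBS.

    alpha            significance level for accepting a change-point
    n_permutations   permutations per test (early stopping applies)
    min_width        minimum windows per segment
    call_threshold   |log2(CN/2)| above which a segment is called
    seed             RNG seed for the permutation test
    """

    alpha: float = 0.01
    n_permutations: int = 10_000
    min_width: int = 2
    call_threshold: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.call_threshold <= 0:
            raise ValueError("call_threshold must be positive")


def _arc_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All circular arcs (i, j] with both arc and complement >= min_width.

    Pairs are produced in lexicographic (i, j) order, which fixes the
    tie-break for the argmax.  Each circular split is enumerated exactly
    once: a split is a pair of cut points in {0, ..., n-1}, so j stops
    at n - 1 (the arc (i, n] is the complement of (0, i] and would be a
    duplicate with an identical t value).
    """
    ii, jj = [], []
    for i in range(n):
        j_lo = i + min_width
        j_hi = min(n - 1, i + n - min_width)
        if j_lo <= j_hi:
            j = np.arange(j_lo, j_hi + 1)
            ii.append(np.full(len(j), i))
            jj.append(j)
    if not ii:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ii), np.concatenate(jj)


def _max_t2_rows(X: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row max squared circular two-sample t over the given arcs.

    X is (B, n); returns (max_t2[B], argmax pair index[B]).  A zero
    within-arc variance with distinct means yields +inf (a forced split).
    """
    B, n = X.shape
    P = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    S = P[:, -1:]
    SStot = np.sum(X * X, axis=1, keepdims=True)
    m = (jj - ii).astype(np.float64)
    s = P[:, jj] - P[:, ii]
    mean_in = s / m
    mean_out = (S - s) / (n - m)
    ssw = SStot - m * mean_in**2 - (n - m) * mean_out**2
    ssw = np.maximum(ssw, 0.0)
    diff2 = (mean_in - mean_out) ** 2
    if n > 2:
        denom = (ssw / (n - 2)) * (1.0 / m + 1.0 / (n - m))
    else:
        denom = np.zeros_like(ssw)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(denom > 0, diff2 / np.where(denom > 0, denom, 1.0), np.where(diff2 > 0, np.inf, 0.0))
    k = np.argmax(t2, axis=1)
    return t2[np.arange(B), k], k


def max_t_arc(x: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Best circular arc (i, j] of ``x`` by the two-sample t-statistic.

    Returns (i, j, |t|); ties resolved in favour of the lexicographically
    first (i, j).  This is the quantity the permutation test thresholds.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    ii, jj = _arc_pairs(n, min_width)
    if len(ii) == 0:
        raise ValueError(f"no admissible arc for n={n}, min_width={min_width}")
    t2, k = _max_t2_rows(x[None, :], ii, jj)
    return int(ii[k[0]]), int(jj[k[0]]), float(np.sqrt(t2[0]))


def _split_significant(
    x: np.ndarray, params: SegmentationParams, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Permutation-test the best arc of ``x``; return it if accepted.

    Early stopping in both directions: the test aborts as soon as the
    exceedance count can no longer come in under alpha, and accepts
    early once an upper binomial confidence bound on the p-value (the
    Clopper-Pearson-style (e + 4) / done at >= 500 permutations) falls
    below alpha.
    """
    n = len(x)
    if n < 2 * params.min_width:
        return None
    ii, jj = _arc_pairs(n, params.min_width)
    if len(ii) == 0:
        return None
    t2_obs, k = _max_t2_rows(x[None, :], ii, jj)
    t2_obs = float(t2_obs[0])
    i, j = int(ii[k[0]]), int(jj[k[0]])
    if not np.isfinite(t2_obs):
        return i, j  # exact step: no permutation can match it
    if t2_obs == 0.0:
        return None

    nperm = params.n_permutations
    max_exceed = params.alpha * nperm
    batch_cap = max(1, min(250, int(4e6 / max(len(ii), 1))))
    exceed = 0
    done = 0
    while done < nperm:
        # small first batches let clearly-null segments bail out cheaply
        b = min(50 if done < 100 else batch_cap, nperm - done)
        Xp = rng.permuted(np.tile(x, (b, 1)), axis=1)
        t2_perm, _ = _max_t2_rows(Xp, ii, jj)
        exceed += int(np.sum(t2_perm >= t2_obs))
        done += b
        if exceed > max_exceed:
            return None  # p cannot fall below alpha
        lower = max(exceed - 3.0 * np.sqrt(exceed + 1.0), 0.0) / done
        if lower > params.alpha:
            return None  # p clearly above alpha
        if done >= 500 and (exceed + 4.0) / done < params.alpha:
            break  # clearly significant
    p = (exceed + 1) / (done + 1)
    return (i, j) if p < params.alpha else None


def cbs_segment(
    cn: np.ndarray,
    params: SegmentationParams | None = None,
    rng: np.random.Generator | None = None,
    eps: float = 1e-3,
) -> list[tuple[int, int]]:
    """Segment one chromosome's CN vector; returns half-open index spans.

    The two-sample t-statistic is computed on log2(cn + eps), where eps
    (1 / median window count when called through ``segment_profile``)
    stabilizes zero-count windows; segment boundaries are reported as
    (start, end) window-index pairs partitioning [0, n).  A vector
    shorter than 2 * min_width (or with no accepted split) comes back
    as a single segment.
    """
    params = params or SegmentationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cn = np.asarray(cn, dtype=np.float64)
    n = len(cn)
    if n == 0:
        return []
    y = np.log2(np.maximum(cn, 0.0) + eps)

    boundaries: set[int] = {0, n}

    def recurse(lo: int, hi: int) -> None:
        seg = y[lo:hi]
        if len(seg) < 2 * params.min_width or np.all(seg == seg[0]):
            return
        hit = _split_significant(seg, params, rng)
        if hit is None:
            return
        i, j = hit
        cuts = sorted({lo + i, lo + j} & set(range(lo + 1, hi)))
        if not cuts:
            return
        boundaries.update(cuts)
        pieces = [lo] + cuts + [hi]
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, n)
    b = sorted(boundaries)
    return list(zip(b[:-1], b[1:]))


def segment_profile(
    profile: BinnedProfile, params: SegmentationParams | None = None
) -> list[Segment]:
    """Run CBS per chromosome on a normalized profile; segments in genome order.

    Blacklisted windows are skipped; a segment spans from the start of
    its first usable window to the end of its last one, bridging any
    masked windows in between.  ``mean_cn`` is the plain mean of the
    member windows' CN estimates.
    """
    params = params or SegmentationParams()
    if "cn" not in profile.df.columns:
        raise ValueError("profile has no 'cn' column; run median_normalize first")
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    df = profile.df
    if "corrected_count" in df.columns:
        med_count = float(np.nanmedian(df.loc[~df["blacklisted"], "corrected_count"]))
        eps = 1.0 / med_count if med_count > 0 else 1e-3
    else:
        eps = 1e-3
    for chrom in profile.genome.names:
        sel = (df["chrom"] == chrom) & ~df["blacklisted"]
        sub = df.loc[sel]
        if len(sub) == 0:
            continue
        cn = sub["cn"].to_numpy(dtype=np.float64)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(cn) < 2:
            spans = [(0, len(cn))]
        else:
            spans = cbs_segment(cn, params, rng, eps=eps)
        for lo, hi in spans:
            segments.append(
                Segment(
                    chrom=chrom,
                    first=lo,
                    last=hi - 1,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_cn=float(np.mean(cn[lo:hi])),
                )
            )
    return segments


def call_segments(segments: Sequence[Segment], call_threshold: float = 0.35) -> list[Segment]:
    """Assign gain/loss/neutral calls by the log2(CN/2) threshold.

    The inequality is strict: a segment sitting exactly on the
    threshold (CN = 2 * 2**0.35 = 2.549...) stays neutral.  A zero-mean
    segment is a loss (log2 ratio of -inf).
    """
    out = []
    for seg in segments:
        s = Segment(seg.chrom, seg.first, seg.last, seg.start, seg.end, seg.mean_cn)
        if s.log2ratio > call_threshold:
            s.call = "gain"
        elif s.log2ratio < -call_threshold:
            s.call = "loss"
        else:
            s.call = "neutral"
        out.append(s)
    return out


def segments_to_calls(segments: Sequence[Segment]) -> list[CNAInterval]:
    """Collapse called segments into CNA intervals.

    Directly adjacent segments on the same chromosome with the same
    non-neutral call merge into one interval (copy number becomes the
    window-weighted mean); neutral segments are dropped and break
    adjacency, so gain-neutral-gain yields two intervals.
    """
    calls: list[CNAInterval] = []
    acc: list[Segment] | None = None

    def flush() -> None:
        nonlocal acc
        if acc:
            w = np.array([s.n_windows for s in acc], dtype=float)
            cn = float(np.average([s.mean_cn for s in acc], weights=w))
            calls.append(
                CNAInterval(acc[0].chrom, acc[0].start, acc[-1].end, acc[0].call, cn)
            )
        acc = None

    for seg in segments:
        if seg.call == "neutral":
            flush()
            continue
        if (
            acc
            and seg.chrom == acc[-1].chrom
            and seg.call == acc[-1].call
            and seg.first == acc[-1].last + 1
        ):
            acc.append(seg)
        else:
            flush()
            acc = [seg]
    flush()
    return calls


def plot_profile(
    profile: BinnedProfile,
    segments: Sequence[Segment] | None = None,
    path: str | Path | None = None,
    ylim: tuple[float, float] = (-2.5, 2.5),
):
    """Genome-wide line profile: log2(CN/2) per window, segments overlaid.

    Windows are ordered along the x-axis by genomic position with an
    alternating background shade per chromosome; horizontal lines mark
    segment means and dashed lines the calling thresholds.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.df
    cn = df["cn"].to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log2(cn / 2.0)
    x = np.arange(len(df))

    fig, ax = plt.subplots(figsize=(14, 4))
    # alternating chromosome backgrounds
    chrom_first: dict[str, int] = {}
    for idx, c in enumerate(df["chrom"]):
        chrom_first.setdefault(c, idx)
    ordered = sorted(chrom_first, key=chrom_first.get)
    for rank, c in enumerate(ordered):
        lo = chrom_first[c]
        hi = chrom_first[ordered[rank + 1]] if rank + 1 < len(ordered) else len(df)
        if rank % 2:
            ax.axvspan(lo - 0.5, hi - 0.5, color="#dce9f5", zorder=0)
        ax.text((lo + hi) / 2, ylim[1] * 0.92, c.replace("chr", ""), ha="center", fontsize=7)
    ax.scatter(x, np.clip(y, *ylim), s=3, c="#555555", zorder=2)
    if segments:
        # map (chrom, usable-window index) -> global x
        for seg in segments:
            sel = (df["chrom"] == seg.chrom) & ~df["blacklisted"]
            gidx = np.flatnonzero(sel.to_numpy())
            lo, hi = gidx[seg.first], gidx[seg.last]
            color = {"gain": "#1f77b4", "loss": "#d62728", "neutral": "#2ca02c"}[seg.call]
            ax.hlines(np.clip(seg.log2ratio, *ylim), lo - 0.5, hi + 0.5, color=color, lw=2, zorder=3)
    for thr in (0.35, -0.35):
        ax.axhline(thr, ls="--", lw=0.8, c="black", zorder=1)
    ax.set_xlim(-0.5, len(df) - 0.5)
    ax.set_ylim(*ylim)
    ax.set_xlabel("window (genome order)")
    ax.set_ylabel("log2(CN / 2)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
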