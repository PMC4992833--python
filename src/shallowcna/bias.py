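"""Representation-bias metrics for window read counts.

The central statistic is a Poisson-corrected adjacent-window variance:
read counts in genomically adjacent windows are differenced, scaled by
the mean count ``a``, and averaged,

    V = 1 / (2 * n_pairs) * sum_pairs ((x_i - x_{i+1}) / a)^2  -  1 / a

For independent Poisson(a) counts, E[((x_i - x_{i+1}) / a)^2] = 2 / a,
so the subtracted 1/a exactly cancels the variance contributed by
random read generation during sequencing; what remains measures the
variance introduced by sample processing — dominantly whole-genome
amplification.  The statistic can go slightly negative on sub-Poisson
input (a constant profile gives exactly -1/a).

Adjacency is genomic: pairs spanning a chromosome boundary or touching
a blacklisted window are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinnedProfile

__all__ = [
    "VarianceResult",
    "read_count_variance",
    "profile_read_count_variance",
    "welch_t_test",
    "bias_summary",
]


@dataclass(frozen=True)
class VarianceResult:
    statistic: float
    n_pairs: int
    mean_count: float


def read_count_variance(
    counts: np.ndarray, pair_mask: np.ndarray | None = None
) -> VarianceResult:
    """Poisson-corrected scaled adjacent-window variance of ``counts``.

    ``counts`` are the usable window counts in genome order;
    ``pair_mask`` (length n-1 boolean) marks which adjacent pairs are
    genomically contiguous (default: all).  Needs at least one usable
    pair and a positive mean count.
    """
    x = np.asarray(counts, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 windows")
    if pair_mask is None:
        pair_mask = np.ones(n - 1, dtype=bool)
    pair_mask = np.asarray(pair_mask, dtype=bool)
    if pair_mask.shape != (n - 1,):
        raise ValueError("pair_mask must have length n - 1")
    n_pairs = int(pair_mask.sum())
    if n_pairs == 0:
        raise ValueError("no usable adjacent pairs")
    a = float(np.mean(x))
    if a <= 0:
        raise ValueError("mean count must be positive")
    d = np.diff(x)[pair_mask] / a
    stat = float(np.sum(d * d) / (2.0 * n_pairs) - 1.0 / a)
    return VarianceResult(statistic=stat, n_pairs=n_pairs, mean_count=a)


def profile_read_count_variance(
    profile: BinnedProfile, use_corrected: bool = False
) -> VarianceResult:
    """The variance statistic of a binned profile.

    Works on raw counts by default (``use_corrected=True`` switches to
    GC/mappability-corrected counts).  Blacklisted windows are dropped
    and pairs spanning a chromosome boundary or a masked gap are
    excluded from the sum.
    """
    df = profile.df
    usable = profile.usable
    col = "corrected_count" if use_corrected else "raw_count"
    if use_corrected and "corrected_count" not in df.columns:
        raise ValueError("profile has no corrected counts")
    x = df[col].to_numpy(dtype=np.float64)[usable]
    chrom = df["chrom"].to_numpy()[usable]
    idx = np.flatnonzero(usable)
    # adjacency: consecutive usable windows, same chromosome, no masked gap
    pair_mask = (chrom[:-1] == chrom[1:]) & (np.diff(idx) == 1)
    return read_count_variance(x, pair_mask)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, two-sided p).

    Degenerate input with zero variance in both groups is resolved by
    convention: equal means give p = 1, distinct means p = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bias_summary(profiles: Sequence[BinnedProfile], labels: Sequence[str] | None = None,
                 use_corrected: bool = False) -> pd.DataFrame:
    """Per-sample variance statistics plus quartiles for box plotting.

    Returns one row per sample with columns ``label, statistic,
    n_pairs, mean_count``; quartile summaries per label group are
    available via ``df.groupby('label')['statistic'].describe()``.
    """
    if labels is None:
        labels = [f"sample_{i}" for i in range(len(profiles))]
    if len(labels) != len(profiles):
        raise ValueError("labels and profiles must align")
    rows = []
    for label, p in zip(labels, profiles):
        r = profile_read_count_variance(p, use_corrected=use_corrected)
        rows.append(
            {"label": label, "statistic": r.statistic, "n_pairs": r.n_pairs,
             "mean_count": r.mean_count}
        )
    return pd.DataFrame(rows)
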