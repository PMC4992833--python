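"""Benchmark scoring of CNA calls against a truth set.

A call is a true positive only when it corresponds to a truth event of
the same direction on the same chromosome, overlaps it, and differs
from it in size by at most 10%.  The size rule is what penalizes the
classic failure mode of biased amplification: calling a whole
chromosome where only an arm-level event exists counts as a false
positive, not as a sloppy true positive.  Each truth event can be
matched by at most one call (greedy, by descending overlap); sensitivity
is TP / |truth| and PPV is TP / (TP + FP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CNAInterval

__all__ = ["EvaluationResult", "match_calls", "summarize_replicates"]


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    match_table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def ppv(self) -> float:
        """TP / (TP + FP); NaN when there are no calls at all."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan


def match_calls(
    calls: Sequence[CNAInterval],
    truth: Sequence[CNAInterval],
    size_tol: float = 0.10,
) -> EvaluationResult:
    """Score calls against truth under the 10%-size matching rule.

    A (call, truth) pair is eligible when chromosome and direction
    agree, the intervals overlap, and |size_call - size_truth| /
    size_truth <= size_tol.  Eligible pairs are assigned greedily by
    descending overlap, one call per truth event; leftover calls are
    false positives and unmatched truth events false negatives.  The
    result's match table records the assignment per call and per truth
    event.
    """
    pairs = []  # (overlap, call_idx, truth_idx)
    for ci, call in enumerate(calls):
        for ti, tr in enumerate(truth):
            if call.chrom != tr.chrom or call.direction != tr.direction:
                continue
            ov = call.overlap(tr)
            if ov <= 0:
                continue
            if abs(call.size - tr.size) / tr.size > size_tol:
                continue
            pairs.append((ov, ci, ti))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    call_to_truth: dict[int, int] = {}
    matched_truth: set[int] = set()
    for ov, ci, ti in pairs:
        if ci in call_to_truth or ti in matched_truth:
            continue
        call_to_truth[ci] = ti
        matched_truth.add(ti)

    tp = len(call_to_truth)
    fp = len(calls) - tp
    fn = len(truth) - tp

    rows = []
    for ci, call in enumerate(calls):
        ti = call_to_truth.get(ci)
        rows.append(
            {
                "kind": "call",
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "direction": call.direction,
                "status": "TP" if ti is not None else "FP",
                "matched_index": ti if ti is not None else -1,
            }
        )
    for ti, tr in enumerate(truth):
        if ti not in matched_truth:
            rows.append(
                {
                    "kind": "truth",
                    "chrom": tr.chrom,
                    "start": tr.start,
                    "end": tr.end,
                    "direction": tr.direction,
                    "status": "FN",
                    "matched_index": -1,
                }
            )
    return EvaluationResult(tp=tp, fp=fp, fn=fn, match_table=pd.DataFrame(rows))


def summarize_replicates(
    results: Sequence[EvaluationResult],
) -> dict[str, float | int | bool]:
    """Mean and sample SD (n-1) of sensitivity and PPV across replicates.

    Replicates with undefined PPV (no calls) are excluded from the PPV
    aggregate and counted in ``ppv_undefined``; a single replicate gets
    SD 0 with ``single_replicate`` flagged.
    """
    if not results:
        raise ValueError("need at least one replicate")
    sens = np.array([r.sensitivity for r in results], dtype=np.float64)
    ppvs = np.array([r.ppv for r in results], dtype=np.float64)
    defined = np.isfinite(ppvs)

    def mean_sd(v: np.ndarray) -> tuple[float, float]:
        if len(v) == 0:
            return math.nan, math.nan
        return float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    sens_mean, sens_sd = mean_sd(sens[np.isfinite(sens)])
    ppv_mean, ppv_sd = mean_sd(ppvs[defined])
    return {
        "n_replicates": len(results),
        "sensitivity_mean": sens_mean,
        "sensitivity_sd": sens_sd,
        "ppv_mean": ppv_mean,
        "ppv_sd": ppv_sd,
        "ppv_undefined": int((~defined).sum()),
        "single_replicate": len(results) == 1,
    }
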