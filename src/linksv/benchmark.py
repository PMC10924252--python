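"""Evaluation of detected candidate SVs against simulated truth.

For every truth event the candidate calls that overlap at least
``min_overlap`` (default 0.9) of the truth interval are ranked by overlap
(descending) then by scaled breakpoint error (ascending); the top call is the
match.  The scaled error,

    (|call.start - truth.start| + |call.end - truth.end|) / m,

is the combined breakpoint discrepancy in units of genomic windows.  A truth
event is a true positive at threshold T windows iff it is matched and its
scaled error is <= T; sensitivity is TP / (TP + FN), stratified by SV type,
size and window size at thresholds of 15, 20 and 25 windows by default.
Insertions have a zero-length reference footprint, so they are evaluated
against a +/- one-window interval around the insertion point (detection is
window-limited).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import CandidateSV
from .simulate import SimulatedSV


@dataclass(frozen=True)
class EvaluationConfig:
    """Matching rule parameters (minimum overlap 0.9; thresholds in windows)."""

    min_overlap: float = 0.9
    error_thresholds: Tuple[int, ...] = (15, 20, 25)
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if any(t <= 0 for t in self.error_thresholds):
            raise ValueError("error thresholds must be positive")


def truth_interval(sv: SimulatedSV, window_size: int) -> Tuple[int, int]:
    """Reference interval a truth event is scored against.

    Deletions/inversions use their footprint; insertions use +/- one window
    around the breakpoint, clipped at zero.
    """
    if sv.type == "insertion":
        return max(0, sv.ref_start - window_size), sv.ref_start + window_size
    return sv.ref_start, sv.ref_end


def overlap_fraction(truth: Tuple[int, int], call: Tuple[int, int]) -> float:
    """Overlap of ``call`` with ``truth``, relative to the truth length."""
    t0, t1 = truth
    c0, c1 = call
    if t1 <= t0:
        raise ValueError("truth interval must have positive length")
    return max(0, min(t1, c1) - max(t0, c0)) / (t1 - t0)


def scaled_error(truth: Tuple[int, int], call: Tuple[int, int], window_size: int) -> float:
    """Summed absolute breakpoint discrepancies in units of windows."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    t0, t1 = truth
    c0, c1 = call
    return (abs(c0 - t0) + abs(c1 - t1)) / window_size


@dataclass
class EvaluationRecord:
    """Per-truth-event match outcome with TP/FN status per error threshold."""

    truth: SimulatedSV
    matched_call: Optional[CandidateSV]
    overlap: float
    error: Optional[float]  # scaled breakpoint error, windows; None if unmatched
    status: Dict[int, str]  # threshold -> "TP" | "FN"


def match_and_score(
    truth_set: Sequence[SimulatedSV],
    call_set: Sequence[CandidateSV],
    config: EvaluationConfig = EvaluationConfig(),
) -> Tuple[List[EvaluationRecord], pd.DataFrame]:
    """Match every truth event to its best call and tabulate sensitivity.

    A call may match several truth events, but each truth event takes at most
    one call (best overlap, ties broken by smaller scaled error).  Returns
    the per-event records and a sensitivity table stratified by
    (sv_type, sv_size, window_size, error_threshold).
    """
    m = config.window_size
    records: List[EvaluationRecord] = []
    for sv in truth_set:
        t_iv = truth_interval(sv, m)
        best: Optional[Tuple[float, float, CandidateSV]] = None
        best_overlap_any = 0.0
        for call in call_set:
            if call.chrom != sv.chrom:
                continue
            ov = overlap_fraction(t_iv, (call.start, call.end))
            best_overlap_any = max(best_overlap_any, ov)
            if ov < config.min_overlap:
                continue
            err = scaled_error(t_iv, (call.start, call.end), m)
            key = (-ov, err)
            if best is None or key < (-best[0], best[1]):
                best = (ov, err, call)
        if best is None:
            records.append(
                EvaluationRecord(sv, None, best_overlap_any, None,
                                 {t: "FN" for t in config.error_thresholds})
            )
        else:
            ov, err, call = best
            status = {t: ("TP" if err <= t else "FN") for t in config.error_thresholds}
            records.append(EvaluationRecord(sv, call, ov, err, status))
    return records, sensitivity_table(records, config)


def sensitivity_table(
    records: Sequence[EvaluationRecord], config: EvaluationConfig
) -> pd.DataFrame:
    """Sensitivity TP/(TP+FN) per (sv_type, sv_size, window_size, threshold)."""
    rows = []
    strata = sorted({(r.truth.type, r.truth.size) for r in records})
    for sv_type, size in strata:
        sel = [r for r in records if r.truth.type == sv_type and r.truth.size == size]
        for t in config.error_thresholds:
            tp = sum(1 for r in sel if r.status[t] == "TP")
            rows.append(
                {
                    "sv_type": sv_type,
                    "sv_size": size,
                    "window_size": config.window_size,
                    "error_threshold": t,
                    "n_truth": len(sel),
                    "n_tp": tp,
                    "sensitivity": tp / len(sel) if sel else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def overall_sensitivity(records: Sequence[EvaluationRecord], threshold: int) -> float:
    """Pooled TP/(TP+FN) over all truth events at one error threshold."""
    if not records:
        return float("nan")
    tp = sum(1 for r in records if r.status[threshold] == "TP")
    return tp / len(records)


def precision_table(
    records: Sequence[EvaluationRecord],
    call_set: Sequence[CandidateSV],
    config: EvaluationConfig = EvaluationConfig(),
) -> pd.DataFrame:
    """Secondary report: fraction of calls matched to some truth event."""
    rows = []
    for t in config.error_thresholds:
        matched_calls = {
            id(r.matched_call)
            for r in records
            if r.matched_call is not None and r.status[t] == "TP"
        }
        rows.append(
            {
                "error_threshold": t,
                "n_calls": len(call_set),
                "n_matched": len(matched_calls),
                "precision": len(matched_calls) / len(call_set) if call_set else float("nan"),
            }
        )
    return pd.DataFrame(rows)
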