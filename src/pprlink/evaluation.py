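"""Linkage-quality and blocking-efficiency metrics, plus a sweep harness.

Quality is pairwise over the incremental protocol: every insert that
returned an existing PID is one predicted pair (query record, matched
record); it counts as a true positive iff the query's ground-truth
partner carries that PID.  Efficiency is the reduction ratio
RR = 1 - (#candidates with blocking) / (#records in database),
computed per insert and averaged; RR = 0.999 means a 1000-fold
reduction of comparisons.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "score_linkage", "reduction_ratio", "insert_results_frame", "sweep"]


@dataclass
class MetricsReport:
    """Counts and derived metrics of one linkage run."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    recall: float = 0.0
    precision: float = 0.0
    f1: float = 0.0
    no_predictions: bool = False  # precision reported as 0 by convention
    avg_candidates: float = 0.0
    reduction_ratio: float = 0.0
    mean_insert_time: float = 0.0
    extra: Dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision, "f1": self.f1,
            "avg_candidates": self.avg_candidates,
            "reduction_ratio": self.reduction_ratio,
            "mean_insert_time": self.mean_insert_time,
        }
        d.update(self.extra)
        return d


def score_linkage(results: Sequence, truth_pairs: Dict[str, str]) -> MetricsReport:
    """Score a run's insert results against ground-truth pairs.

    ``truth_pairs`` maps duplicate record id -> original record id.
    Possible matches are counted as non-matches (they do not reuse a
    PID); records referenced by the truth but absent from the results
    raise an error.
    """
    seen = {r.record_id for r in results if r.record_id is not None}
    pid_of: Dict[str, str] = {}
    for r in results:
        if r.record_id is not None and r.pid is not None:
            pid_of[r.record_id] = r.pid
    for b, a in truth_pairs.items():
        if b not in seen or a not in seen:
            raise ValueError(f"truth pair ({b},{a}) not covered by the results")

    tp = fp = fn = 0
    for r in results:
        partner = truth_pairs.get(r.record_id)
        if r.pid is None:  # rejected as invalid: its true pair is unrecoverable
            if partner is not None:
                fn += 1
            continue
        if r.status == "matched":
            if partner is not None and pid_of.get(partner) == r.pid:
                tp += 1
            else:
                fp += 1
                if partner is not None:
                    fn += 1  # the true pair was missed as well
        else:
            if partner is not None:
                fn += 1

    recall = tp / (tp + fn) if (tp + fn) else 1.0
    no_pred = (tp + fp) == 0
    precision = 0.0 if no_pred else tp / (tp + fp)
    if no_pred and not truth_pairs:
        precision = 1.0
    f1 = 0.0 if (recall + precision) == 0 else 2 * recall * precision / (recall + precision)

    report = MetricsReport(
        tp=tp, fp=fp, fn=fn,
        recall=recall, precision=precision, f1=f1,
        no_predictions=no_pred,
    )
    _fill_efficiency(report, results)
    return report


def _fill_efficiency(report: MetricsReport, results: Sequence) -> None:
    cands = [r.candidate_count for r in results if r.pid is not None]
    report.avg_candidates = float(np.mean(cands)) if cands else 0.0
    report.reduction_ratio = reduction_ratio_of_results(results)
    times = [sum(r.timings.values()) for r in results if r.timings]
    report.mean_insert_time = float(np.mean(times)) if times else 0.0


def reduction_ratio(avg_candidates: float, store_size: float) -> float:
    """RR = 1 - #candidates-with-blocking / #records-in-database."""
    if store_size <= 0:
        raise ValueError("store size must be positive")
    return 1.0 - avg_candidates / store_size


def reduction_ratio_of_results(results: Sequence) -> float:
    """Per-insert RR against the store size at that moment, averaged.

    Inserts into an empty store are skipped (no comparison to avoid);
    a candidate count of 0 contributes the boundary value RR = 1.
    """
    ratios = [
        reduction_ratio(r.candidate_count, r.store_size_before)
        for r in results
        if r.pid is not None and r.store_size_before > 0
    ]
    return float(np.mean(ratios)) if ratios else 0.0


def insert_results_frame(results: Sequence) -> pd.DataFrame:
    """Tabular view of a run (one row per processed record)."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in results],
            "pid": [r.pid for r in results],
            "status": [r.status for r in results],
            "similarity": [r.similarity for r in results],
            "matched_record_id": [r.matched_record_id for r in results],
            "candidates": [r.candidate_count for r in results],
            "store_size": [r.store_size_before for r in results],
        }
    )


def sweep(engine_factory, configs: Sequence[dict], dataset, truth_pairs: Dict[str, str]) -> pd.DataFrame:
    """Run one linkage per config on a fresh store and tabulate metrics.

    ``engine_factory(**config)`` must return a fresh LinkageEngine; the
    dataset provides ``raw_records_a()`` / ``raw_records_b()``.  A grid
    of size one reduces to a single scored run.
    """
    rows = []
    for cfg in configs:
        engine = engine_factory(**cfg)
        t0 = time.perf_counter()
        results = engine.batch_link(dataset.raw_records_a())
        results += engine.batch_link(dataset.raw_records_b())
        elapsed = time.perf_counter() - t0
        report = score_linkage(results, truth_pairs)
        row = {**cfg}
        row.update(report.as_dict())
        row["wall_time"] = elapsed
        rows.append(row)
        engine.close()
    return pd.DataFrame(rows)
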