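"""Benchmark scoring: recall / precision / F1, provirus recovery, FP rate.

A fragment counts as "predicted viral" if the pipeline emitted any
prediction for it (full, trimmed or partial). A provirus truth counts as
recovered when some prediction covers at least half of its bp span; a
prediction matching no truth at that level is a false positive
(many-to-one: one long prediction may recover several truths).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from viroscan.features import Region


@dataclass(frozen=True)
class PRF:
    recall: float
    precision: float
    f1: float
    degenerate: bool = False


@dataclass(frozen=True)
class BenchmarkResult:
    group: str
    length_bp: int
    replicate: int
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float


def prf(tp: int, fp: int, fn: int) -> PRF:
    """Recall, precision and F1 from confusion counts.

    Any undefined ratio (zero denominator) yields 0 and sets the degenerate
    flag.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if precision + recall == 0:
        return PRF(recall, precision, 0.0, True)
    return PRF(recall, precision, 2 * precision * recall / (precision + recall), degenerate)


def _overlap_bp(a: Region, b: Region) -> int:
    return max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1)


def provirus_match(pred: Region, truth: Region) -> bool:
    """True iff the prediction recovers >= 50% of the truth's bp span."""
    if pred.contig_id != truth.contig_id:
        raise ValueError("prediction and truth are on different contigs")
    return _overlap_bp(pred, truth) / truth.span_bp >= 0.5


def match_proviruses(
    predictions: Sequence[Region], truths: Sequence[Region]
) -> tuple[int, int, int]:
    """(tp, fp, fn) under the >=50%-recovery rule, matched per contig.

    Each truth recovered by any prediction is a TP; a prediction recovering
    no truth is an FP; unrecovered truths are FNs.
    """
    tp = fn = 0
    matched_preds: set[int] = set()
    for truth in truths:
        hit = False
        for i, pred in enumerate(predictions):
            if pred.contig_id == truth.contig_id and provirus_match(pred, truth):
                hit = True
                matched_preds.add(i)
        if hit:
            tp += 1
        else:
            fn += 1
    fp = len(predictions) - len(matched_preds)
    return tp, fp, fn


def false_positive_rate(
    flagged_nonviral: Iterable[str], n_nonviral: int
) -> float:
    """Percent of non-viral fragments with any emitted prediction."""
    if n_nonviral <= 0:
        raise ValueError("n_nonviral must be positive")
    return 100.0 * len(set(flagged_nonviral)) / n_nonviral


def fragment_benchmark(
    labels: Mapping[str, int],
    predicted_viral: Iterable[str],
    group: str = "all",
    length_bp: int = 0,
    replicate: int = 0,
) -> BenchmarkResult:
    """Fragment-level confusion for one labeled set.

    ``labels`` maps contig id -> 1 (viral) / 0 (non-viral); ``predicted_viral``
    is the set of contig ids with any emitted prediction.
    """
    pred = set(predicted_viral)
    unknown = pred - set(labels)
    if unknown:
        raise ValueError(f"predictions for unlabeled contigs: {sorted(unknown)[:3]}")
    tp = sum(1 for cid, lab in labels.items() if lab == 1 and cid in pred)
    fp = sum(1 for cid, lab in labels.items() if lab == 0 and cid in pred)
    fn = sum(1 for cid, lab in labels.items() if lab == 1 and cid not in pred)
    m = prf(tp, fp, fn)
    return BenchmarkResult(group=group, length_bp=length_bp, replicate=replicate,
                           tp=tp, fp=fp, fn=fn,
                           recall=m.recall, precision=m.precision, f1=m.f1)
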