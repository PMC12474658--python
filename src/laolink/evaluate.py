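"""Record-level evaluation of a predicted partition against a gold standard.

The unit of evaluation is the record, not the pair: a record is *positive*
when it belongs to a multi-record cluster (size >= 2) in the respective
partition.  True positives are records positive in both partitions, false
positives in the prediction only, false negatives in the gold only, true
negatives in neither; the four counts always sum to the size of the record
universe.  Precision, recall and F1 follow, with zero denominators mapped
to 0 (logged).  Pair-level metrics are available as a clearly separate
secondary report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import RAW_COLUMNS, Partition

logger = logging.getLogger("laolink")


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float


def round_percent(x: float) -> int:
    """Round a proportion to integer percent, half away from zero."""
    return int(Decimal(x * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def record_confusion(predicted: Partition, gold: Partition) -> ConfusionCounts:
    """Record-level confusion counts; both partitions must cover the same ids."""
    if predicted.record_ids != gold.record_ids:
        diff = sorted(predicted.record_ids ^ gold.record_ids)
        raise ValueError(f"partitions cover different records: {diff[:20]}")
    pred_pos = predicted.linked_records()
    gold_pos = gold.linked_records()
    universe = gold.record_ids
    tp = len(pred_pos & gold_pos)
    fp = len(pred_pos - gold_pos)
    fn = len(gold_pos - pred_pos)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tn=tn, fp=fp, fn=fn, tp=tp)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Precision, recall, F1 with the zero-division-to-zero convention."""
    def _ratio(num, den):
        if den == 0:
            logger.warning("metrics: zero denominator, reporting 0")
            return 0.0
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = _ratio(2 * precision * recall, precision + recall)
    return MetricSet(precision=precision, recall=recall, f1=f1)


def pair_confusion(predicted: Partition, gold: Partition) -> ConfusionCounts:
    """Secondary report: pair-level counts over all unordered record pairs."""
    if predicted.record_ids != gold.record_ids:
        raise ValueError("partitions cover different records")
    def _pairs(p: Partition) -> set:
        out = set()
        for cluster in p.clusters():
            members = sorted(cluster)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    out.add((members[i], members[j]))
        return out

    pp, gp = _pairs(predicted), _pairs(gold)
    n = len(gold.record_ids)
    total = n * (n - 1) // 2
    tp = len(pp & gp)
    fp = len(pp - gp)
    fn = len(gp - pp)
    return ConfusionCounts(tn=total - tp - fp - fn, fp=fp, fn=fn, tp=tp)


@dataclass
class PRCurve:
    points: pd.DataFrame  # columns threshold, precision, recall
    auc: float


def pr_curve(scores: Mapping[str, float], gold: Partition,
             thresholds: Sequence[float] | None = None) -> PRCurve:
    """Record-level precision-recall curve over a score threshold sweep.

    ``scores`` assigns each record a match score (e.g. the maximum posterior
    over its candidate links; records without candidates score 0).  At each
    threshold, records scoring at or above it are the predicted positives.
    AUC is the trapezoid over (recall, precision) sorted by recall, with an
    anchor at recall 0 carrying the precision of the strictest threshold.
    A single-point sweep degenerates to the rectangle precision x recall.
    """
    universe = gold.record_ids
    missing = universe - set(scores)
    scores = dict(scores)
    for rid in missing:
        scores[rid] = 0.0
    gold_pos = gold.linked_records()
    if thresholds is None:
        thresholds = sorted({v for v in scores.values()}, reverse=True)
    if len(thresholds) == 0:
        raise ValueError("empty threshold sweep")
    rows = []
    for t in thresholds:
        pred_pos = {rid for rid, s in scores.items() if s >= t}
        tp = len(pred_pos & gold_pos)
        fp = len(pred_pos - gold_pos)
        fn = len(gold_pos - pred_pos)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append((t, precision, recall))
    pts = pd.DataFrame(rows, columns=["threshold", "precision", "recall"])
    if len(pts) == 1:
        auc = float(pts["precision"].iloc[0] * pts["recall"].iloc[0])
    else:
        anchor_p = pts.sort_values("threshold", ascending=False)["precision"].iloc[0]
        r = np.concatenate([[0.0], pts["recall"].to_numpy()])
        p = np.concatenate([[anchor_p], pts["precision"].to_numpy()])
        order = np.argsort(r, kind="stable")
        auc = float(np.trapezoid(p[order], r[order]))
    return PRCurve(points=pts, auc=auc)


def record_scores_from_pairs(scored_pairs: pd.DataFrame,
                             score_col: str = "posterior") -> dict:
    """Per-record score = maximum score over incident candidate pairs."""
    out: dict = {}
    for _, row in scored_pairs.iterrows():
        s = float(row[score_col])
        for rid in (row["id1"], row["id2"]):
            if s > out.get(rid, -np.inf):
                out[rid] = s
    return out


def cluster_size_table(p: Partition) -> pd.DataFrame:
    """Distribution of multi-record cluster sizes.

    Columns: size, count, pct (share of multi-record clusters), records.
    """
    sizes = [s for s in p.cluster_sizes().values() if s >= 2]
    if not sizes:
        return pd.DataFrame(columns=["size", "count", "pct", "records"])
    counts = pd.Series(sizes).value_counts().sort_index()
    total = counts.sum()
    return pd.DataFrame({
        "size": counts.index,
        "count": counts.to_numpy(),
        "pct": (counts / total * 100).round(1).to_numpy(),
        "records": (counts.index * counts).to_numpy(),
    }).reset_index(drop=True)


def completeness_profile(df: pd.DataFrame,
                         fields: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-field percentage of non-missing values (2-decimal rounding)."""
    if fields is None:
        fields = [c for c in RAW_COLUMNS if c != "record_id" and c in df.columns]
    rows = [(f, round(float(df[f].notna().mean() * 100), 2)) for f in fields]
    return pd.DataFrame(rows, columns=["field", "pct_complete"])


def name_frequency(df: pd.DataFrame, top: int = 10, bottom: int = 5,
                   column: str = "name") -> dict:
    """Most and least frequent names (deterministic tie-break: count then
    lexicographic).  Missing values are excluded and counted separately."""
    values = df[column].dropna()
    counts = values.value_counts()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_rows = ordered[:top]
    bottom_rows = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))[:bottom]
    return {
        "top": pd.DataFrame(top_rows, columns=[column, "count"]),
        "bottom": pd.DataFrame(bottom_rows, columns=[column, "count"]),
        "n_missing": int(df[column].isna().sum()),
    }
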