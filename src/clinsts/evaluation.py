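"""Scoring and error analysis for 0-5 similarity predictions.

The headline metric is the Pearson correlation coefficient (PCC) between
gold and predicted scores.  Error analysis discretizes both into the five
intervals [0,1), [1,2), [2,3), [3,4), [4,5] — a prediction is a true
positive when gold and prediction share an interval, otherwise a false
positive in the predicted interval and a false negative in the gold one —
and computes PCC restricted to gold-score ranges (the low/high extremes
versus the middle of the scale, where averaged two-annotator gold scores
concentrate disagreement).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

INTERVALS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0))
INTERVAL_LABELS = ("[0,1)", "[1,2)", "[2,3)", "[3,4)", "[4,5]")


class UndefinedCorrelationError(ValueError):
    """Raised when a PCC is requested on degenerate data."""


def pearson_correlation(gold: Sequence[float], pred: Sequence[float]) -> float:
    """Sample Pearson r between gold and predicted scores."""
    g = np.asarray(gold, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {p.shape}")
    if g.size < 2:
        raise UndefinedCorrelationError("need at least 2 points for a correlation")
    if np.ptp(g) == 0 or np.ptp(p) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(stats.pearsonr(g, p).statistic)


def average_annotator_scores(a1: Sequence[float], a2: Sequence[float]) -> np.ndarray:
    """Element-wise mean of two annotators' 0-5 scores (the gold standard)."""
    x1 = np.asarray(a1, dtype=np.float64)
    x2 = np.asarray(a2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError("annotator score lists differ in length")
    for name, x in (("annotator 1", x1), ("annotator 2", x2)):
        if x.size and (x.min() < 0 or x.max() > 5):
            raise ValueError(f"{name}: scores outside [0,5]")
    return (x1 + x2) / 2.0


def split_dataset(examples: list, fractions: tuple[float, float, float],
                  seed: int) -> tuple[list, list, list]:
    """Seeded shuffle then contiguous partition with largest-remainder
    rounding; the three parts are disjoint and exhaustive."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    n = len(examples)
    if n < 3:
        raise ValueError("need at least 3 examples to make a 3-way split")
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [examples[i] for i in order]
    a = shuffled[: sizes[0]]
    b = shuffled[sizes[0]: sizes[0] + sizes[1]]
    c = shuffled[sizes[0] + sizes[1]:]
    return a, b, c


def assign_interval(value: float) -> int:
    """Index of the similarity interval; [4,5] is closed at 5."""
    return min(int(np.floor(value)), 4)


@dataclass
class IntervalScore:
    label: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None and r is None:
            return None  # interval empty on both sides: undefined
        p = p or 0.0
        r = r or 0.0
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def gold_count(self) -> int:
        return self.tp + self.fn

    @property
    def pred_count(self) -> int:
        return self.tp + self.fp


def interval_f1(gold: Sequence[float], pred: Sequence[float]) -> list[IntervalScore]:
    """Per-interval precision/recall/F1 under interval-membership matching.

    Predictions are clipped to [0,5] before binning.  An interval with no
    gold and no predicted members has undefined F1 (``None``), not 0.
    """
    g = np.asarray(gold, dtype=np.float64)
    p = np.clip(np.asarray(pred, dtype=np.float64), 0.0, 5.0)
    if g.shape != p.shape:
        raise ValueError("gold and pred differ in length")
    if g.size and (g.min() < 0 or g.max() > 5):
        raise ValueError("gold scores outside [0,5]")
    gbin = np.array([assign_interval(x) for x in g], dtype=int)
    pbin = np.array([assign_interval(x) for x in p], dtype=int)
    scores = []
    for i, label in enumerate(INTERVAL_LABELS):
        tp = int(np.sum((gbin == i) & (pbin == i)))
        fp = int(np.sum((pbin == i) & (gbin != i)))
        fn = int(np.sum((gbin == i) & (pbin != i)))
        scores.append(IntervalScore(label, tp, fp, fn))
    return scores


ScoreRange = tuple[float, float, bool]  # (lo, hi, closed_hi)

DEFAULT_RANGES: dict[str, list[ScoreRange]] = {
    # low/high extremes of the gold scale vs the middle
    "[0,2)+[4,5]": [(0.0, 2.0, False), (4.0, 5.0, True)],
    "[2,4)": [(2.0, 4.0, False)],
}


def _in_ranges(value: float, ranges: list[ScoreRange]) -> bool:
    for lo, hi, closed in ranges:
        if lo <= value < hi or (closed and value == hi):
            return True
    return False


def range_restricted_pcc(gold: Sequence[float], pred: Sequence[float],
                         ranges: Optional[dict[str, list[ScoreRange]]] = None,
                         ) -> dict[str, Optional[float]]:
    """PCC restricted to pairs whose *gold* score falls in each range.

    Degenerate subsets (fewer than 2 points or zero variance) map to
    ``None`` rather than raising.
    """
    if ranges is None:
        ranges = DEFAULT_RANGES
    g = np.asarray(gold, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    out: dict[str, Optional[float]] = {}
    for label, rs in ranges.items():
        mask = np.array([_in_ranges(x, rs) for x in g])
        try:
            out[label] = pearson_correlation(g[mask], p[mask])
        except UndefinedCorrelationError:
            out[label] = None
    return out


@dataclass
class EvalReport:
    """Full evaluation: overall PCC, range-restricted PCCs, interval F1."""

    pcc: float
    range_pcc: dict[str, Optional[float]]
    intervals: list[IntervalScore]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pcc": self.pcc,
            "range_pcc": self.range_pcc,
            "interval_f1": [
                {"interval": s.label, "precision": s.precision,
                 "recall": s.recall, "f1": s.f1,
                 "gold_count": s.gold_count, "pred_count": s.pred_count}
                for s in self.intervals
            ],
        }


def evaluate(gold: Sequence[float], pred: Sequence[float]) -> EvalReport:
    g = np.asarray(gold, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    return EvalReport(
        pcc=pearson_correlation(g, p),
        range_pcc=range_restricted_pcc(g, p),
        intervals=interval_f1(g, p),
        n=int(g.size),
    )
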