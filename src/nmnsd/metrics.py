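"""Binary classification metrics from confusion counts."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConfusionCounts", "percent"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts with the preferred class as positive.

    Indeterminate predictions must be counted as errors by the caller
    (a false negative for a positive example, false positive-free but
    wrong for a negative one — i.e., never a correct count).
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0


def percent(correct: int, total: int) -> float:
    """Percentage of correct outcomes from raw counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * correct / total
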