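"""Binary confusion counts and the derived detection metrics.

Positive class is always SNOW.  Sensitivity is the true-positive rate on
snow images, specificity the true-negative rate on snow-free images.  A
rate whose denominator is zero is reported as ``None`` (missing), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a rate is requested over an empty evaluable set."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> Optional[float]:
        return (self.tp + self.fn) / self.total if self.total else None

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.total if self.total else None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    def to_dict(self, percent: bool = False) -> dict:
        d = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
             "n": self.total}
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if v is not None and percent:
                v = round(100.0 * v, 1)
            d[name] = v
        return d

    @classmethod
    def from_labels(
        cls, y_true: Iterable[bool], y_pred: Iterable[bool]
    ) -> "ConfusionCounts":
        t = np.asarray(list(y_true), dtype=bool)
        p = np.asarray(list(y_pred), dtype=bool)
        if t.shape != p.shape:
            raise ValueError("label arrays must have equal length")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )


def percent(x: Optional[float], digits: int = 1) -> Optional[float]:
    """Rate as a percentage rounded the way the reports print it."""
    return None if x is None else round(100.0 * x, digits)
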