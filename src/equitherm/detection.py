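"""Rider:horse bodyweight ratio and threshold-based group detection.

The ratio is 100 x (rider + saddle weight) / horse weight, in percent.
Detection distinguishes light (L) from heavy (H) rider groups with three
cutoffs placed at the reference sample's mean - SD, mean, and mean + SD;
an observation strictly above the cutoff is called heavy (the positive
class).  Performance is scored as sensitivity, specificity, positive and
negative predictive value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError

__all__ = [
    "bodyweight_ratio",
    "ThresholdSet",
    "ConfusionSummary",
    "make_thresholds",
    "classify_and_score",
    "threshold_sweep",
]


def bodyweight_ratio(rider_kg: float, saddle_kg: float, horse_kg: float) -> float:
    """Rider:horse bodyweight ratio in percent, to one decimal.

    100 x (rider + saddle) / horse.  E.g. the light-group means
    (59.0 kg rider, 4.3 kg saddle, 566.7 kg horse) give 11.2 %.
    """
    if horse_kg <= 0:
        raise ConfigurationError(f"horse weight must be positive, got {horse_kg}")
    if rider_kg < 0 or saddle_kg < 0:
        raise ConfigurationError("rider and saddle weights must be non-negative")
    return round(100.0 * (rider_kg + saddle_kg) / horse_kg, 1)


@dataclass(frozen=True)
class ThresholdSet:
    """Cutoffs at mean - SD, mean, mean + SD of a reference sample."""

    low: float
    mid: float
    high: float
    n: int
    description: str = ""

    def __iter__(self):
        return iter((self.low, self.mid, self.high))

    @property
    def labels(self) -> tuple[str, str, str]:
        return ("m-SD", "mean", "m+SD")


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and derived metrics at one threshold.

    Heavy is the positive class.  Ratios with a zero denominator are
    NaN (undefined), never reported as 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def Se(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else math.nan

    @property
    def Sp(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else math.nan

    @property
    def PPV(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else math.nan

    @property
    def NPV(self) -> float:
        return self.TN / (self.TN + self.FN) if self.TN + self.FN else math.nan

    def metrics(self, ndigits: int | None = None) -> dict[str, float]:
        vals = {"Se": self.Se, "Sp": self.Sp, "PPV": self.PPV, "NPV": self.NPV}
        if ndigits is not None:
            vals = {
                k: (round(v, ndigits) if not math.isnan(v) else v) for k, v in vals.items()
            }
        return vals


def make_thresholds(values, description: str = "") -> ThresholdSet:
    """Mean - SD / mean / mean + SD of the reference values (sample SD, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DimensionError(f"need at least 2 reference values, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return ThresholdSet(low=mean - sd, mid=mean, high=mean + sd, n=v.size, description=description)


def classify_and_score(values_light, values_heavy, threshold: float) -> ConfusionSummary:
    """Score the heavy-vs-light rule "value strictly above threshold -> heavy".

    Ties go to light, the literal reading of "above the threshold".
    """
    light = np.asarray(values_light, dtype=float)
    heavy = np.asarray(values_heavy, dtype=float)
    if light.size == 0 or heavy.size == 0:
        raise DimensionError("both groups must be non-empty")
    tp = int(np.count_nonzero(heavy > threshold))
    fp = int(np.count_nonzero(light > threshold))
    return ConfusionSummary(TP=tp, FP=fp, TN=light.size - fp, FN=heavy.size - tp)


def threshold_sweep(values_light, values_heavy, thresholds: ThresholdSet) -> list[ConfusionSummary]:
    """One ConfusionSummary per cutoff, ordered low -> mid -> high."""
    return [classify_and_score(values_light, values_heavy, t) for t in thresholds]
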