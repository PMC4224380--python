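"""Comparison of nucleosome maps and profiles.

Calls are binarised into per-basepair 0/1 coverage vectors (1 = packaged
by a nucleosome); maps are compared by the Pearson correlation of those
vectors and by per-basepair confusion metrics (positional Accuracy,
Sensitivity, Precision, MCC).  Center lists are compared by the fraction
of one set lying within X nucleotides of the other, and call sets by the
distribution of inter-nucleosome linker lengths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .classify import ConfusionCounts, evaluate_metrics
from .features import InvalidParameterError
from .peaks import NucleosomeCall


class ConstantMapError(ValueError):
    """Correlation of a constant 0/1 map is undefined."""


@dataclass(frozen=True)
class BinaryOccupancyMap:
    """Per-basepair 0/1 coverage vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.int8)
        if arr.ndim != 1 or set(np.unique(arr).tolist()) - {0, 1}:
            raise InvalidParameterError("map must be a 1-D 0/1 vector")
        object.__setattr__(self, "bits", arr)

    @property
    def length(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class MapComparisonReport:
    pearson_r: float
    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    precision: float
    mcc: float


def binarize_calls(calls: Sequence[NucleosomeCall], length: int) -> BinaryOccupancyMap:
    """1 on every basepair covered by a call, 0 elsewhere (1-based calls)."""
    bits = np.zeros(length, dtype=np.int8)
    for c in calls:
        if c.start < 1 or c.end > length:
            raise InvalidParameterError(
                f"call [{c.start}, {c.end}] outside sequence of length {length}"
            )
        bits[c.start - 1 : c.end] = 1
    return BinaryOccupancyMap(bits=bits)


def map_correlation(a: BinaryOccupancyMap, b: BinaryOccupancyMap) -> float:
    """Pearson r of two equal-length 0/1 maps."""
    if a.length != b.length:
        raise InvalidParameterError("maps must have equal length")
    for name, m in (("first", a), ("second", b)):
        if m.bits.min() == m.bits.max():
            raise ConstantMapError(f"{name} map is constant; correlation undefined")
    return float(np.corrcoef(a.bits, b.bits)[0, 1])


def linker_length_distribution(
    calls: Sequence[NucleosomeCall], length: int
) -> Counter:
    """Histogram of gaps between consecutive non-overlapping calls.

    Terminal gaps (before the first and after the last call) are excluded.
    """
    ordered = sorted(calls, key=lambda c: c.start)
    hist: Counter = Counter()
    for prev, nxt in zip(ordered, ordered[1:]):
        gap = nxt.start - prev.end - 1
        if gap < 0:
            raise InvalidParameterError(
                f"overlapping calls at [{prev.start},{prev.end}] and "
                f"[{nxt.start},{nxt.end}]"
            )
        hist[gap] += 1
    return hist


def within_x_fraction(
    query_centers: Sequence[int], reference_centers: Sequence[int], x: int
) -> float:
    """Fraction of query centers with a reference center within <= x bp."""
    if x < 0:
        raise InvalidParameterError("x must be non-negative")
    if len(query_centers) == 0:
        raise InvalidParameterError("empty query center list")
    if len(reference_centers) == 0:
        return 0.0
    ref = np.sort(np.asarray(reference_centers))
    q = np.asarray(query_centers)
    idx = np.searchsorted(ref, q)
    left = ref[np.clip(idx - 1, 0, len(ref) - 1)]
    right = ref[np.clip(idx, 0, len(ref) - 1)]
    nearest = np.minimum(np.abs(q - left), np.abs(q - right))
    return float(np.mean(nearest <= x))


def positional_accuracy(
    pred: BinaryOccupancyMap, ref: BinaryOccupancyMap
) -> MapComparisonReport:
    """Per-basepair confusion between a predicted and a reference map.

    TP counts basepairs covered in both maps, TN basepairs covered in
    neither; Accuracy 1 means zero positional error.  pearson_r is NaN
    when either map is constant.
    """
    if pred.length != ref.length:
        raise InvalidParameterError("maps must have equal length")
    p, r = pred.bits, ref.bits
    confusion = ConfusionCounts(
        tp=int(np.sum((p == 1) & (r == 1))),
        tn=int(np.sum((p == 0) & (r == 0))),
        fp=int(np.sum((p == 1) & (r == 0))),
        fn=int(np.sum((p == 0) & (r == 1))),
    )
    m = evaluate_metrics(confusion)
    try:
        r_val = map_correlation(pred, ref)
    except ConstantMapError:
        r_val = float("nan")
    return MapComparisonReport(
        pearson_r=r_val,
        confusion=confusion,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        precision=m["precision"],
        mcc=m["mcc"],
    )


def feature_occupancy_correlation(
    features: Sequence[float], occupancy: Sequence[float]
) -> float:
    """Pearson r between per-item feature values and occupancy values."""
    f = np.asarray(features, dtype=float)
    o = np.asarray(occupancy, dtype=float)
    if f.shape != o.shape or f.ndim != 1:
        raise InvalidParameterError("inputs must be equal-length 1-D vectors")
    if len(f) < 3:
        raise InvalidParameterError("need at least 3 observations")
    if np.ptp(f) == 0 or np.ptp(o) == 0:
        raise ConstantMapError("constant input; correlation undefined")
    return float(stats.pearsonr(f, o).statistic)
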