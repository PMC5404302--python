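"""The multi-class threshold rule that turns a scalar discriminant value
into a class prediction.

For each class the median of the training-sample test values is computed;
classes are ordered by ascending median, and the mean of each successive
pair of medians becomes a threshold. With all boundary flags off the rule
is the typical one: a sample with value v is assigned class c_1 if v < t_1,
class c_i if t_{i-1} <= v < t_i, and class c_n if v >= t_{n-1}. Each of the
n-1 inequalities may independently be made strict (the boundary value then
belongs to the lower class instead), giving 2^(n-1) candidate rules; fitting
evaluates them all and keeps the one with the highest training accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = [
    "MulticlassRule",
    "class_medians",
    "compute_thresholds",
    "classify_sample",
    "classify_values",
    "fit_rule",
]

#: A ClassValueTable is any mapping {class label: sequence of test values}.
ClassValueTable = Mapping[Hashable, Sequence[float]]


@dataclass(frozen=True)
class MulticlassRule:
    """Ordered classes, n-1 thresholds, and n-1 boundary-direction flags.

    ``strict_flags[i]`` False means the boundary value ``t_i`` belongs to the
    upper class (v >= t_i moves up); True makes the comparison strict, so the
    boundary value stays with the lower class.
    """

    ordered_classes: tuple[Hashable, ...]
    thresholds: tuple[float, ...]
    strict_flags: tuple[bool, ...]

    def __post_init__(self):
        n = len(self.ordered_classes)
        object.__setattr__(self, "ordered_classes", tuple(self.ordered_classes))
        object.__setattr__(
            self, "thresholds", tuple(float(t) for t in self.thresholds)
        )
        object.__setattr__(
            self, "strict_flags", tuple(bool(f) for f in self.strict_flags)
        )
        if n < 2:
            raise ValueError("rule needs at least 2 classes")
        if len(set(self.ordered_classes)) != n:
            raise ValueError("ordered_classes must be distinct")
        if len(self.thresholds) != n - 1 or len(self.strict_flags) != n - 1:
            raise ValueError("need exactly n-1 thresholds and n-1 flags")
        if any(
            self.thresholds[i] > self.thresholds[i + 1]
            for i in range(len(self.thresholds) - 1)
        ):
            raise ValueError("thresholds must be non-decreasing")

    @property
    def n_classes(self) -> int:
        return len(self.ordered_classes)


def class_medians(values: ClassValueTable) -> list[tuple[Hashable, float]]:
    """Per-class medians, sorted ascending (stable: ties keep input order).

    Even-sized classes use the midpoint of the two central order statistics.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 classes")
    pairs: list[tuple[Hashable, float]] = []
    for label, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"class {label!r} has no test values")
        pairs.append((label, float(np.median(arr))))
    pairs.sort(key=lambda kv: kv[1])  # stable: equal medians keep input order
    return pairs


def compute_thresholds(ordered_medians: Sequence[float]) -> list[float]:
    """Midpoints of successive ordered medians: t_i = (m_i + m_{i+1}) / 2."""
    meds = [float(m) for m in ordered_medians]
    if len(meds) < 2:
        raise ValueError("need at least 2 medians")
    if any(meds[i] > meds[i + 1] for i in range(len(meds) - 1)):
        raise ValueError("medians must be non-decreasing")
    return [(meds[i] + meds[i + 1]) / 2.0 for i in range(len(meds) - 1)]


def _class_indices(
    v: np.ndarray, thresholds: Sequence[float], strict_flags: Sequence[bool]
) -> np.ndarray:
    """Index into ordered_classes for each value: number of thresholds passed."""
    idx = np.zeros(v.shape, dtype=np.intp)
    for t, strict in zip(thresholds, strict_flags):
        idx += (v > t) if strict else (v >= t)
    return idx


def classify_sample(v: float, rule: MulticlassRule) -> Hashable:
    """Assign a finite scalar test value to exactly one class."""
    if not np.isfinite(v):
        raise ValueError("test value must be finite")
    idx = int(
        _class_indices(np.asarray([v], dtype=float), rule.thresholds, rule.strict_flags)[0]
    )
    return rule.ordered_classes[idx]


def classify_values(values: np.ndarray, rule: MulticlassRule) -> np.ndarray:
    """Vectorized :func:`classify_sample`; returns an object array of labels."""
    v = np.asarray(values, dtype=float)
    idx = _class_indices(v, rule.thresholds, rule.strict_flags)
    classes = np.asarray(rule.ordered_classes, dtype=object)
    return classes[idx]


def fit_rule(values: ClassValueTable) -> tuple[MulticlassRule, float]:
    """Fit the threshold rule to per-class training test values.

    All 2^(n-1) boundary-flag vectors are evaluated; the one with maximal
    training accuracy wins, ties broken lexicographically with the all-False
    vector first.
    """
    ordered = class_medians(values)
    labels = [label for label, _ in ordered]
    thresholds = compute_thresholds([m for _, m in ordered])
    v_parts, y_parts = [], []
    pos = {label: i for i, label in enumerate(labels)}
    for label, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        v_parts.append(arr)
        y_parts.append(np.full(arr.size, pos[label], dtype=np.intp))
    v = np.concatenate(v_parts)
    y = np.concatenate(y_parts)
    flags, acc = _best_flags(v, y, thresholds)
    return MulticlassRule(tuple(labels), tuple(thresholds), flags), acc


def _best_flags(
    v: np.ndarray, y: np.ndarray, thresholds: Sequence[float]
) -> tuple[tuple[bool, ...], float]:
    """Exhaustive search over boundary-flag vectors, vectorized per vector."""
    ge = v[:, None] >= np.asarray(thresholds)[None, :]
    gt = v[:, None] > np.asarray(thresholds)[None, :]
    best_flags: tuple[bool, ...] | None = None
    best_acc = -1.0
    n_samples = v.size
    for flags in product((False, True), repeat=len(thresholds)):
        cols = [gt[:, i] if f else ge[:, i] for i, f in enumerate(flags)]
        idx = np.sum(cols, axis=0, dtype=np.intp) if cols else np.zeros(
            n_samples, dtype=np.intp
        )
        acc = float(np.mean(idx == y))
        if acc > best_acc:  # lexicographic enumeration: first max wins
            best_acc = acc
            best_flags = flags
    assert best_flags is not None
    return best_flags, best_acc


def fit_rule_from_codes(
    v: np.ndarray, codes: np.ndarray, class_labels: Sequence[Hashable]
) -> tuple[MulticlassRule, float]:
    """Fast path used inside evolution: values + integer class codes.

    ``codes[k]`` indexes ``class_labels``; every class must be represented.
    Equivalent to building the class-value table and calling :func:`fit_rule`.
    """
    v = np.asarray(v, dtype=float)
    n = len(class_labels)
    meds = np.empty(n)
    for c in range(n):
        sel = v[codes == c]
        if sel.size == 0:
            raise ValueError(f"class {class_labels[c]!r} has no test values")
        meds[c] = np.median(sel)
    order = np.argsort(meds, kind="stable")
    thresholds = compute_thresholds(meds[order].tolist())
    # recode truth into positions along the ordered axis
    rank = np.empty(n, dtype=np.intp)
    rank[order] = np.arange(n)
    y = rank[codes]
    flags, acc = _best_flags(v, y, thresholds)
    labels = tuple(class_labels[i] for i in order)
    return MulticlassRule(labels, tuple(thresholds), flags), acc
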