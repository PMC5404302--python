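"""Accuracy and feature-set stability metrics.

Two accuracy formulas: balanced accuracy (mean of sensitivity and
specificity) for binary classifiers, and plain fraction-correct for the
multi-class setting. Feature-selection stability is the set adaptation of
the Tanimoto coefficient,

    S(s, s') = 1 - (|s| + |s'| - 2|s ∩ s'|) / (|s| + |s'| - |s ∩ s'|),

which equals the Jaccard index |s ∩ s'| / |s ∪ s'|: 1 for identical sets,
0 for disjoint ones. The stability of a collection of selected feature sets
(e.g. one per cross-validation fold) is the mean Tanimoto over all
unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Sequence

__all__ = [
    "ConfusionCounts",
    "balanced_accuracy",
    "multiclass_accuracy",
    "tanimoto",
    "stability",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.tp + self.fn + self.tn + self.fp < 1:
            raise ValueError("confusion counts must describe at least one sample")


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2 = (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive samples: sensitivity undefined (TP+FN=0)")
    if c.tn + c.fp == 0:
        raise ValueError("no negative samples: specificity undefined (TN+FP=0)")
    return (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp)) / 2.0


def multiclass_accuracy(
    predicted: Sequence[Hashable], truth: Sequence[Hashable]
) -> float:
    """Fraction of correct predictions: correct / (correct + incorrect)."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if not truth:
        raise ValueError("cannot compute accuracy of zero predictions")
    correct = sum(p == t for p, t in zip(predicted, truth))
    return correct / len(truth)


def tanimoto(s: Iterable[Hashable], s2: Iterable[Hashable]) -> float:
    """Tanimoto similarity between two non-empty feature sets."""
    a, b = set(s), set(s2)
    if not a or not b:
        raise ValueError("tanimoto is undefined for empty feature sets")
    inter = len(a & b)
    return 1.0 - (len(a) + len(b) - 2 * inter) / (len(a) + len(b) - inter)


def stability(sets: Sequence[Iterable[Hashable]]) -> float:
    """Mean pairwise Tanimoto over all unordered pairs of feature sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("stability needs at least 2 feature sets")
    pairs = list(combinations(sets, 2))
    return sum(tanimoto(a, b) for a, b in pairs) / len(pairs)
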