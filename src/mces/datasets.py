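"""Labeled expression datasets: the samples × features container consumed by
preprocessing, evolution, and cross-validation.

The matrix is stored samples × features (rows = samples) as float64; class
labels are one per sample, in sample order. Class identity is hashable and
compared by equality; the canonical class order is first appearance in the
label vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd


@dataclass
class LabeledDataset:
    """A numeric feature matrix with per-sample class labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_samples, n_features)
        Feature values, float64.
    feature_names : sequence of str
        One unique identifier per column.
    labels : sequence of hashable
        One class label per row.
    sample_ids : sequence of str, optional
        Row identifiers; defaults to ``s1..sN``.
    """

    matrix: np.ndarray
    feature_names: list[str]
    labels: list[Hashable]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x features)")
        self.feature_names = [str(f) for f in self.feature_names]
        self.labels = list(self.labels)
        n, p = self.matrix.shape
        if len(self.labels) != n:
            raise ValueError(
                f"label count ({len(self.labels)}) != sample count ({n})"
            )
        if len(self.feature_names) != p:
            raise ValueError(
                f"feature-name count ({len(self.feature_names)}) != column count ({p})"
            )
        if len(set(self.feature_names)) != p:
            dupes = sorted(
                {f for f in self.feature_names if self.feature_names.count(f) > 1}
            )
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.classes) < 2:
            raise ValueError("dataset must contain at least 2 classes")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[Hashable]:
        """Distinct class labels in first-appearance order."""
        seen: dict[Hashable, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_sizes(self) -> dict[Hashable, int]:
        sizes: dict[Hashable, int] = {c: 0 for c in self.classes}
        for lab in self.labels:
            sizes[lab] += 1
        return sizes

    def label_codes(self) -> np.ndarray:
        """Integer class codes in canonical (first-appearance) class order."""
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[lab] for lab in self.labels], dtype=np.intp)

    def column_env(self) -> dict[str, np.ndarray]:
        """Mapping feature name -> column vector, for expression evaluation."""
        return {
            name: self.matrix[:, j] for j, name in enumerate(self.feature_names)
        }

    # -- derived datasets --------------------------------------------------

    def subset_samples(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledDataset(
            matrix=self.matrix[idx],
            feature_names=list(self.feature_names),
            labels=[self.labels[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def subset_features(self, names: Sequence[str]) -> "LabeledDataset":
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [index[f] for f in names]
        return LabeledDataset(
            matrix=self.matrix[:, cols],
            feature_names=list(names),
            labels=list(self.labels),
            sample_ids=list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.sample_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, labels: Sequence[Hashable]
    ) -> "LabeledDataset":
        """Build from a samples × features DataFrame and a label vector."""
        return cls(
            matrix=frame.to_numpy(dtype=float),
            feature_names=[str(c) for c in frame.columns],
            labels=list(labels),
            sample_ids=[str(i) for i in frame.index],
        )
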