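"""Expression-data preprocessing: low-count filtering, log transform, and
expert-knowledge feature pre-ranking by one-way ANOVA F-statistic.

The pipeline mirrors common RNA-Seq practice: features never observed at a
raw count of at least 5 in any sample are removed, counts (or FPKM) are
transformed with log2(x + 1), and an "expert knowledge" feature subset — the
top-k features by between-class F-statistic with p below alpha — is supplied
to the evolutionary search to bias feature-leaf sampling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import LabeledDataset

__all__ = [
    "filter_low_counts",
    "log_transform",
    "expert_knowledge_features",
]

MIN_COUNT = 5


def filter_low_counts(raw: LabeledDataset, min_count: int = MIN_COUNT) -> LabeledDataset:
    """Drop features whose raw count never reaches ``min_count`` in any sample.

    Entries must be non-negative integers (integral floats accepted).
    Idempotent; sample order and labels are unchanged.
    """
    x = raw.matrix
    if np.any(x < 0):
        raise ValueError("raw counts must be non-negative")
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("raw counts must be integers")
    keep = np.max(x, axis=0) >= min_count
    names = [f for f, k in zip(raw.feature_names, keep) if k]
    if not names:
        raise ValueError(f"no feature reaches a count of {min_count} in any sample")
    return raw.subset_features(names)


def log_transform(d: LabeledDataset) -> LabeledDataset:
    """Entrywise log2(x + 1); requires non-negative entries."""
    if np.any(d.matrix < 0):
        raise ValueError("log transform requires non-negative entries")
    return LabeledDataset(
        matrix=np.log2(d.matrix + 1.0),
        feature_names=list(d.feature_names),
        labels=list(d.labels),
        sample_ids=list(d.sample_ids),
    )


def expert_knowledge_features(
    d: LabeledDataset, k: int = 100, alpha: float = 0.05
) -> list[str]:
    """Top-k features by one-way ANOVA F-statistic with p-value below alpha.

    Returns feature names ordered by descending F (ties by name), at most k
    of them. Features with undefined F (e.g. zero within-class variance with
    zero between-class variance) are excluded. Requires every class to have
    at least 2 samples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = d.label_codes()
    for c, label in enumerate(d.classes):
        if np.sum(codes == c) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
    groups = [d.matrix[codes == c, :] for c in range(d.n_classes)]
    with np.errstate(divide="ignore", invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = stats.f_oneway(*groups, axis=0)
    f_stat = np.asarray(f_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)
    eligible = np.isfinite(f_stat) & np.isfinite(p_val) & (p_val < alpha)
    ranked = sorted(
        (
            (-f_stat[j], d.feature_names[j])
            for j in np.flatnonzero(eligible)
        ),
    )
    return [name for _, name in ranked[:k]]
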