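"""Repeated stratified k-fold cross-validation of the evolutionary
classifier, with per-fold best-classifier selection and aggregation of
test accuracy, selected-feature counts, and Tanimoto stability.

Each of the r×k train/test evaluations fits everything — the expert-
knowledge feature screen and the evolved classifier (expression + frozen
threshold rule) — on the training split only, then applies the fitted
classifier unchanged to the held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .evolution import Classifier, EvolutionConfig, run_levels
from .metrics import multiclass_accuracy, stability
from .model import prepare_blocks, select_best

__all__ = [
    "FoldPlan",
    "FoldRecord",
    "CVResult",
    "make_folds",
    "run_cv",
    "feature_frequency",
]


@dataclass(frozen=True)
class FoldPlan:
    """r repetitions of a stratified k-fold partition of the sample index."""

    reps: int
    folds: int
    test_indices: tuple[tuple[np.ndarray, ...], ...]  # [rep][fold] -> indices
    seed: int | None = None

    @property
    def n_evaluations(self) -> int:
        return self.reps * self.folds

    def splits(self, n_samples: int):
        """Yield (rep, fold, train_idx, test_idx) in deterministic order."""
        everything = np.arange(n_samples)
        for rep in range(self.reps):
            for fold in range(self.folds):
                test = self.test_indices[rep][fold]
                mask = np.ones(n_samples, dtype=bool)
                mask[test] = False
                yield rep, fold, everything[mask], test


def make_folds(
    labels: Sequence[Hashable], r: int = 10, k: int = 5, seed: int | None = None
) -> FoldPlan:
    """Stratified fold plan: r repetitions × k folds, deterministic per seed.

    Every class must have at least k samples so each training fold retains
    all classes.
    """
    labels = list(labels)
    if r < 1 or k < 2:
        raise ValueError("need r >= 1 repetitions and k >= 2 folds")
    counts: dict[Hashable, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    small = sorted((str(c) for c, n in counts.items() if n < k))
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=object)
    plans = []
    for _ in range(r):
        state = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
        plans.append(
            tuple(test for _, test in skf.split(np.zeros(len(labels)), y))
        )
    return FoldPlan(reps=r, folds=k, test_indices=tuple(plans), seed=seed)


@dataclass(frozen=True)
class FoldRecord:
    rep: int
    fold: int
    accuracy: float
    features: frozenset[str]
    classifier: Classifier


@dataclass
class CVResult:
    """Per-fold records plus the aggregates reported for the protocol."""

    records: list[FoldRecord]
    mean_accuracy: float = field(init=False)
    tanimoto_stability: float = field(init=False)
    mean_n_features: float = field(init=False)

    def __post_init__(self):
        if not self.records:
            raise ValueError("CVResult needs at least one fold record")
        accs = [rec.accuracy for rec in self.records]
        self.mean_accuracy = float(np.mean(accs))
        self.mean_n_features = float(
            np.mean([len(rec.features) for rec in self.records])
        )
        nonempty = [rec.features for rec in self.records if rec.features]
        self.tanimoto_stability = (
            stability(nonempty) if len(nonempty) >= 2 else float("nan")
        )

    def feature_sets(self) -> list[frozenset[str]]:
        return [rec.features for rec in self.records]

    def summary(self) -> str:
        lines = [
            "Cross-validation summary",
            "------------------------",
            f"Evaluations:          {len(self.records)}",
            f"Mean test accuracy:   {self.mean_accuracy:.4f}",
            f"Tanimoto stability:   {self.tanimoto_stability:.4f}",
            f"Mean selected genes:  {self.mean_n_features:.2f}",
        ]
        return "\n".join(lines)


def run_cv(
    dataset: LabeledDataset,
    evo_config: EvolutionConfig,
    fold_plan: FoldPlan,
    seed: int | None = None,
) -> CVResult:
    """Run the full protocol: per fold, evolve on the training split and
    score the selected best classifier on the held-out split."""
    if seed is None:
        seed = evo_config.seed
    master = np.random.default_rng(seed)
    records: list[FoldRecord] = []
    for rep, fold, train_idx, test_idx in fold_plan.splits(dataset.n_samples):
        train = dataset.subset_samples(train_idx)
        test = dataset.subset_samples(test_idx)
        rng = np.random.default_rng(int(master.integers(2**31)))
        blocks = prepare_blocks(train, evo_config)
        archives = run_levels(train, evo_config, rng, blocks=blocks)
        best = select_best(archives[-1].members)
        predicted = list(best.predict(test.column_env()))
        acc = multiclass_accuracy(predicted, list(test.labels))
        records.append(
            FoldRecord(
                rep=rep,
                fold=fold,
                accuracy=acc,
                features=best.feature_set,
                classifier=best,
            )
        )
    return CVResult(records)


def feature_frequency(
    runs: Iterable[Iterable[str]], min_count: int = 2
) -> list[tuple[str, int]]:
    """Count how often each feature appears across runs' selected sets,
    keeping features seen in at least ``min_count`` runs; sorted by
    descending count, then name."""
    runs = [set(r) for r in runs]
    if not runs:
        raise ValueError("feature_frequency needs at least one run")
    counts: dict[str, int] = {}
    for s in runs:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    kept = [(f, n) for f, n in counts.items() if n >= min_count]
    kept.sort(key=lambda fn: (-fn[1], fn[0]))
    return kept
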