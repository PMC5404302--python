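"""Model/Results interface over the evolutionary classifier engine.

``CESModel`` holds a labeled dataset plus an :class:`EvolutionConfig`;
``fit()`` runs the (possibly multi-level) Pareto tournament and returns a
``CESResults`` carrying the per-level archives, the best classifier, and a
``summary()`` table. Prediction applies the best classifier's expression
and its frozen threshold rule to new samples.
"""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .evolution import (
    Classifier,
    EvolutionConfig,
    ParetoArchive,
    run_levels,
)
from .expressions import BuildingBlockSet
from .preprocess import expert_knowledge_features

__all__ = ["CESModel", "CESResults", "select_best"]


def select_best(archive: Sequence[Classifier]) -> Classifier:
    """Archive member with maximal training accuracy; ties broken by fewest
    building blocks, then lexicographically smallest expression string."""
    members = list(archive)
    if not members:
        raise ValueError("cannot select from an empty archive")
    return min(
        members,
        key=lambda m: (-m.fitness.accuracy, m.fitness.complexity, m.expression),
    )


def prepare_blocks(
    dataset: LabeledDataset, config: EvolutionConfig
) -> BuildingBlockSet:
    """Build the building-block vocabulary, with expert-knowledge biasing
    when ``config.expert_k`` > 0 and any feature passes the F-test screen."""
    preferred = None
    if config.expert_k and config.expert_k > 0:
        expert = expert_knowledge_features(
            dataset, k=config.expert_k, alpha=config.expert_alpha
        )
        if expert:
            preferred = tuple(expert)
    return BuildingBlockSet(
        feature_names=tuple(dataset.feature_names),
        operators=config.operators,
        constant_range=config.constant_range,
        preferred_features=preferred,
        preference_bias=config.expert_bias,
    )


class CESModel:
    """Evolutionary symbolic-discriminant classifier for multi-class data.

    Parameters
    ----------
    dataset : LabeledDataset
        Training data: samples × features with one class label per sample.
    config : EvolutionConfig, optional
        Evolution parameters; keyword overrides may be given instead.
    """

    def __init__(self, dataset: LabeledDataset, config: EvolutionConfig | None = None,
                 **overrides):
        if config is None:
            config = EvolutionConfig(**overrides)
        elif overrides:
            from dataclasses import replace

            config = replace(config, **overrides)
        self.dataset = dataset
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        labels: Sequence[Hashable],
        config: EvolutionConfig | None = None,
        **overrides,
    ) -> "CESModel":
        """Build from a samples × features DataFrame and a label vector."""
        return cls(LabeledDataset.from_frame(frame, labels), config, **overrides)

    def fit(self, seed: int | None = None) -> "CESResults":
        """Run the Pareto tournament (all configured levels) and return results."""
        if seed is None:
            seed = self.config.seed
        rng = np.random.default_rng(seed)
        blocks = prepare_blocks(self.dataset, self.config)
        archives = run_levels(self.dataset, self.config, rng, blocks=blocks)
        return CESResults(self, archives, seed)


class CESResults:
    """Results of a fitted :class:`CESModel`."""

    def __init__(self, model: CESModel, archives: list[ParetoArchive],
                 seed: int | None):
        self.model = model
        self.archives = archives
        self.seed = seed

    @property
    def archive(self) -> ParetoArchive:
        """The archive of the highest Pareto level."""
        return self.archives[-1]

    @property
    def front(self) -> list[Classifier]:
        """Final-level Pareto front, sorted by ascending complexity."""
        return sorted(self.archive.members, key=lambda m: m.fitness.complexity)

    @property
    def best(self) -> Classifier:
        """Highest-accuracy classifier of the final level."""
        return select_best(self.archive.members)

    @property
    def selected_features(self) -> list[str]:
        """Features appearing in the best classifier's expression."""
        return sorted(self.best.feature_set)

    def predict(self, data) -> np.ndarray:
        """Predict class labels for a LabeledDataset, DataFrame, or mapping."""
        if isinstance(data, pd.DataFrame):
            env = {c: data[c].to_numpy(dtype=float) for c in data.columns}
        elif isinstance(data, LabeledDataset):
            env = data.column_env()
        else:
            env = data
        return self.best.predict(env)

    def score(self, data: LabeledDataset) -> float:
        """Fraction of correct predictions on a labeled dataset."""
        from .metrics import multiclass_accuracy

        return multiclass_accuracy(list(self.predict(data)), list(data.labels))

    def front_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accuracy": m.fitness.accuracy,
                "complexity": m.fitness.complexity,
                "n_features": len(m.feature_set),
                "expression": m.expression,
            }
            for m in self.front
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the final front and best classifier."""
        best = self.best
        lines = [
            "Computational Evolution Classifier Results",
            "==========================================",
            f"Classes:            {', '.join(map(str, self.model.dataset.classes))}",
            f"Samples x features: {self.model.dataset.n_samples} x "
            f"{self.model.dataset.n_features}",
            f"Pareto levels:      {len(self.archives)}",
            f"Seed:               {self.seed}",
            "",
            "Final-level Pareto front (accuracy vs building blocks):",
        ]
        frame = self.front_frame()
        lines.append(frame.to_string(index=False))
        lines += [
            "",
            f"Best classifier (training accuracy {best.fitness.accuracy:.4f}, "
            f"{best.fitness.complexity} building blocks):",
            f"  expression: {best.expression}",
            f"  class order: {list(best.rule.ordered_classes)}",
            f"  thresholds:  {[round(t, 6) for t in best.rule.thresholds]}",
            f"  strict flags: {list(best.rule.strict_flags)}",
            f"  selected features: {', '.join(self.selected_features) or '(none)'}",
        ]
        return "\n".join(lines)
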