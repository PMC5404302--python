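"""Pareto-optimized evolution of symbolic discriminant classifiers on a
toroidal grid.

Fitness is two-objective: training classification accuracy (maximize) and
model complexity, the building-block count of the expression (minimize).
Solutions live on a D×D toroidal lattice; in each generation every cell that
Pareto-dominates all eight of its Moore neighbors repopulates those eight
cells with mutated copies of itself (each copy re-fitted and re-scored).
The update is synchronous over a frozen copy of the previous generation,
with deterministic conflict resolution when several dominators target the
same cell. An external elitist archive keeps the Pareto front over every
classifier ever evaluated.

A "Pareto level" chains runs: the archive surviving level L seeds the
initial grid of level L+1, emulating restarts that start from previously
discovered building blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .datasets import LabeledDataset
from .expressions import (
    BuildingBlockSet,
    MutationRates,
    Node,
    count_building_blocks,
    mutate,
    random_tree,
    tree_to_string,
)
from .rules import MulticlassRule, classify_values, fit_rule_from_codes

__all__ = [
    "FitnessRecord",
    "Classifier",
    "SolutionGrid",
    "EvolutionConfig",
    "dominates",
    "pareto_front",
    "neighborhood",
    "tournament_step",
    "evolve",
    "run_levels",
    "ParetoArchive",
]


@dataclass(frozen=True)
class FitnessRecord:
    """Accuracy in [0, 1] and complexity = building-block count >= 1."""

    accuracy: float
    complexity: int

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        if self.complexity < 1:
            raise ValueError("complexity must be >= 1")


@dataclass(frozen=True)
class Classifier:
    """An evolved unit: expression tree + fitted threshold rule + fitness."""

    tree: Node
    rule: MulticlassRule
    fitness: FitnessRecord

    @property
    def feature_set(self) -> frozenset[str]:
        return frozenset(self.tree.features())

    @property
    def expression(self) -> str:
        return tree_to_string(self.tree)

    def predict(self, env) -> np.ndarray:
        """Predict class labels from a column environment or dataset."""
        if isinstance(env, LabeledDataset):
            env = env.column_env()
        values = np.atleast_1d(np.asarray(self.tree.evaluate(env), dtype=float))
        return classify_values(values, self.rule)


def dominates(a: FitnessRecord, b: FitnessRecord) -> bool:
    """Pareto domination: a is no worse in both objectives, better in one."""
    if a.accuracy < b.accuracy or a.complexity > b.complexity:
        return False
    return a.accuracy > b.accuracy or a.complexity < b.complexity


def pareto_front(solutions: Sequence[Classifier]) -> list[Classifier]:
    """Members not dominated by any other member; input order preserved."""
    if len(solutions) == 0:
        raise ValueError("pareto_front of an empty solution list")
    out = []
    for i, s in enumerate(solutions):
        if not any(
            dominates(t.fitness, s.fitness) for j, t in enumerate(solutions) if j != i
        ):
            out.append(s)
    return out


@dataclass
class SolutionGrid:
    """D×D toroidal lattice of classifiers."""

    cells: list[list[Classifier]]

    def __post_init__(self):
        d = len(self.cells)
        if d < 3 or any(len(row) != d for row in self.cells):
            raise ValueError("grid must be square with dimension >= 3")

    @property
    def dimension(self) -> int:
        return len(self.cells)

    def __getitem__(self, rc: tuple[int, int]) -> Classifier:
        r, c = rc
        return self.cells[r][c]

    def flatten(self) -> list[Classifier]:
        return [clf for row in self.cells for clf in row]


_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def neighborhood(grid: SolutionGrid, row: int, col: int) -> list[tuple[int, int]]:
    """The 8 Moore neighbors with toroidal wrap-around."""
    d = grid.dimension
    if not (0 <= row < d and 0 <= col < d):
        raise IndexError(f"cell ({row}, {col}) outside {d}x{d} grid")
    return [((row + dr) % d, (col + dc) % d) for dr, dc in _MOORE]


@dataclass(frozen=True)
class EvolutionConfig:
    """Evolution run parameters.

    Defaults follow the production setting (36×36 grid, 1000 generations);
    tests and desk-scale experiments pass smaller values.
    """

    grid_dimension: int = 36
    generations: int = 1000
    mutation_rates: MutationRates = field(default_factory=MutationRates)
    max_initial_depth: int = 4
    pareto_levels: int = 1
    operators: tuple[str, ...] = ("+", "-", "*", "/")
    constant_range: tuple[float, float] = (-10.0, 10.0)
    expert_k: int = 100
    expert_alpha: float = 0.05
    expert_bias: float = 0.8
    archive_cap: int = 500
    seed: int | None = None

    def __post_init__(self):
        if self.grid_dimension < 3:
            raise ValueError("grid_dimension must be >= 3")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.pareto_levels < 1:
            raise ValueError("pareto_levels must be >= 1")
        if self.max_initial_depth < 1:
            raise ValueError("max_initial_depth must be >= 1")
        if not isinstance(self.mutation_rates, MutationRates):
            object.__setattr__(
                self, "mutation_rates", MutationRates(**dict(self.mutation_rates))
            )


class ParetoArchive:
    """Elitist archive: the Pareto front over everything ever evaluated.

    At most one member is kept per (accuracy, complexity) point (first seen
    wins), so the archive is exactly a front. If the cap is exceeded the
    interior member in the tightest accuracy gap is dropped; the extremes of
    the front are never truncated.
    """

    def __init__(self, cap: int = 500):
        self.cap = cap
        self._members: list[Classifier] = []

    def __len__(self) -> int:
        return len(self._members)

    @property
    def members(self) -> list[Classifier]:
        return list(self._members)

    @property
    def best_accuracy(self) -> float:
        return max(m.fitness.accuracy for m in self._members)

    def add(self, clf: Classifier) -> bool:
        f = clf.fitness
        for m in self._members:
            mf = m.fitness
            if dominates(mf, f) or (
                mf.accuracy == f.accuracy and mf.complexity == f.complexity
            ):
                return False
        self._members = [
            m for m in self._members if not dominates(f, m.fitness)
        ]
        self._members.append(clf)
        if len(self._members) > self.cap:
            self._truncate()
        return True

    def update(self, classifiers: Iterable[Classifier]) -> None:
        for clf in classifiers:
            self.add(clf)

    def _truncate(self) -> None:
        order = sorted(
            range(len(self._members)),
            key=lambda i: self._members[i].fitness.accuracy,
        )
        gaps = {}
        for pos in range(1, len(order) - 1):
            i = order[pos]
            gap = (
                self._members[order[pos + 1]].fitness.accuracy
                - self._members[order[pos - 1]].fitness.accuracy
            )
            gaps[i] = gap
        drop = min(gaps, key=lambda i: (gaps[i], i))
        del self._members[drop]


def _evaluate_tree(
    tree: Node,
    env: dict[str, np.ndarray],
    codes: np.ndarray,
    class_labels: Sequence[Hashable],
) -> Classifier:
    """Fit the threshold rule for a tree on training data and score it."""
    values = np.atleast_1d(np.asarray(tree.evaluate(env), dtype=float))
    if values.size == 1 and codes.size > 1:  # constant-only expression
        values = np.full(codes.size, float(values[0]))
    rule, acc = fit_rule_from_codes(values, codes, class_labels)
    return Classifier(
        tree=tree,
        rule=rule,
        fitness=FitnessRecord(accuracy=acc, complexity=count_building_blocks(tree)),
    )


def _random_grid(
    blocks: BuildingBlockSet,
    env: dict[str, np.ndarray],
    codes: np.ndarray,
    class_labels: Sequence[Hashable],
    config: EvolutionConfig,
    rng: np.random.Generator,
    seed_members: Sequence[Classifier] = (),
) -> SolutionGrid:
    d = config.grid_dimension
    total = d * d
    pool: list[Classifier] = []
    if seed_members:
        if len(seed_members) >= total:
            pool = [seed_members[i % len(seed_members)] for i in range(total)]
        else:
            pool = list(seed_members)
    while len(pool) < total:
        tree = random_tree(blocks, config.max_initial_depth, rng)
        pool.append(_evaluate_tree(tree, env, codes, class_labels))
    cells = [[pool[r * d + c] for c in range(d)] for r in range(d)]
    return SolutionGrid(cells)


def tournament_step(
    grid: SolutionGrid,
    blocks: BuildingBlockSet,
    env: dict[str, np.ndarray],
    codes: np.ndarray,
    class_labels: Sequence[Hashable],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[SolutionGrid, list[Classifier]]:
    """One synchronous domination-tournament generation.

    Returns the successor grid and the list of newly created (mutated,
    re-fitted) classifiers. Cells not written by any dominator persist.
    """
    d = grid.dimension
    old = grid.cells
    dominators: list[tuple[int, int]] = []
    for r in range(d):
        for c in range(d):
            f = old[r][c].fitness
            if all(
                dominates(f, old[nr][nc].fitness)
                for nr, nc in neighborhood(grid, r, c)
            ):
                dominators.append((r, c))

    # target cell -> winning dominator (higher accuracy, lower complexity,
    # then smaller (row, col))
    claims: dict[tuple[int, int], tuple[int, int]] = {}
    for r, c in dominators:
        for target in neighborhood(grid, r, c):
            cur = claims.get(target)
            if cur is None:
                claims[target] = (r, c)
            else:
                fa, fb = old[r][c].fitness, old[cur[0]][cur[1]].fitness
                if (-fa.accuracy, fa.complexity, (r, c)) < (
                    -fb.accuracy,
                    fb.complexity,
                    cur,
                ):
                    claims[target] = (r, c)

    new_cells = [list(row) for row in old]
    offspring: list[Classifier] = []
    for target in sorted(claims):
        wr, wc = claims[target]
        child_tree = mutate(old[wr][wc].tree, blocks, config.mutation_rates, rng)
        child = _evaluate_tree(child_tree, env, codes, class_labels)
        new_cells[target[0]][target[1]] = child
        offspring.append(child)
    return SolutionGrid(new_cells), offspring


def _prepare(dataset: LabeledDataset):
    sizes = dataset.class_sizes()
    small = [c for c, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    return dataset.column_env(), dataset.label_codes(), dataset.classes


def evolve(
    dataset: LabeledDataset,
    config: EvolutionConfig,
    rng: np.random.Generator,
    blocks: BuildingBlockSet | None = None,
    seed_members: Sequence[Classifier] = (),
) -> tuple[SolutionGrid, ParetoArchive]:
    """Run one evolution: random (or seeded) grid, ``config.generations``
    tournament steps, external Pareto archive over everything evaluated."""
    env, codes, class_labels = _prepare(dataset)
    if blocks is None:
        blocks = BuildingBlockSet(
            feature_names=tuple(dataset.feature_names),
            operators=config.operators,
            constant_range=config.constant_range,
        )
    grid = _random_grid(blocks, env, codes, class_labels, config, rng, seed_members)
    archive = ParetoArchive(cap=config.archive_cap)
    archive.update(grid.flatten())
    for _ in range(config.generations):
        grid, offspring = tournament_step(
            grid, blocks, env, codes, class_labels, config, rng
        )
        archive.update(offspring)
    return grid, archive


def run_levels(
    dataset: LabeledDataset,
    config: EvolutionConfig,
    rng: np.random.Generator,
    blocks: BuildingBlockSet | None = None,
) -> list[ParetoArchive]:
    """Chained Pareto levels: each level's archive seeds the next level's
    initial grid (tiled into cells, remainder random). Returns all archives."""
    archives: list[ParetoArchive] = []
    seed_members: Sequence[Classifier] = ()
    for _ in range(config.pareto_levels):
        _, archive = evolve(dataset, config, rng, blocks=blocks,
                            seed_members=seed_members)
        archives.append(archive)
        seed_members = archive.members
    return archives
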