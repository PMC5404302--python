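"""Pareto fitness, grid tournament, archive, and multi-level evolution."""

import numpy as np
import pytest

from mces.datasets import LabeledDataset
from mces.evolution import (
    Classifier,
    EvolutionConfig,
    FitnessRecord,
    ParetoArchive,
    SolutionGrid,
    dominates,
    evolve,
    neighborhood,
    pareto_front,
    run_levels,
    tournament_step,
)
from mces.expressions import BuildingBlockSet, Constant, Feature
from mces.rules import MulticlassRule


def clf(accuracy, complexity, name="x"):
    return Classifier(
        tree=Feature(name),
        rule=MulticlassRule(("a", "b"), (0.0,), (False,)),
        fitness=FitnessRecord(accuracy, complexity),
    )


def brute_force_front(solutions):
    out = []
    for i, s in enumerate(solutions):
        if not any(
            dominates(t.fitness, s.fitness)
            for j, t in enumerate(solutions)
            if j != i
        ):
            out.append(s)
    return out


class TestDominates:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0.9, 5), (0.8, 10), True),
            ((0.9, 5), (0.9, 5), False),
            ((0.9, 10), (0.8, 5), False),
            ((0.8, 5), (0.9, 10), False),
            ((0.9, 5), (0.9, 6), True),
            ((0.9, 5), (0.8, 5), True),
        ],
    )
    def test_pairs(self, a, b, expected):
        assert dominates(FitnessRecord(*a), FitnessRecord(*b)) is expected


class TestParetoFront:
    def test_hand_example(self):
        sols = [clf(0.9, 5), clf(0.8, 3), clf(0.7, 10)]
        front = pareto_front(sols)
        assert [(s.fitness.accuracy, s.fitness.complexity) for s in front] == [
            (0.9, 5),
            (0.8, 3),
        ]

    def test_single_solution(self):
        s = clf(0.5, 2)
        assert pareto_front([s]) == [s]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])

    def test_oracle_equivalence_and_no_dominated_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            m = int(rng.integers(1, 25))
            sols = [
                clf(float(rng.integers(0, 11)) / 10, int(rng.integers(1, 12)))
                for _ in range(m)
            ]
            front = pareto_front(sols)
            assert [id(s) for s in front] == [id(s) for s in brute_force_front(sols)]
            for a in front:
                for b in front:
                    if a is not b:
                        assert not dominates(a.fitness, b.fitness)


class TestNeighborhood:
    def grid(self, d):
        return SolutionGrid([[clf(0.5, 1) for _ in range(d)] for _ in range(d)])

    def test_center_3x3(self):
        cells = neighborhood(self.grid(3), 1, 1)
        assert sorted(cells) == [
            (0, 0), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1), (2, 2)
        ]

    def test_corner_wraps(self):
        cells = neighborhood(self.grid(5), 0, 0)
        assert len(set(cells)) == 8
        assert (4, 4) in cells

    def test_every_cell_of_4x4_has_8_distinct(self):
        g = self.grid(4)
        for r in range(4):
            for c in range(4):
                cells = neighborhood(g, r, c)
                assert len(cells) == 8
                assert len(set(cells)) == 8
                assert (r, c) not in cells

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            neighborhood(self.grid(3), 3, 0)


def _env_setup(dataset):
    return dataset.column_env(), dataset.label_codes(), dataset.classes


class TestTournamentStep:
    def _blocks(self, dataset):
        return BuildingBlockSet(feature_names=tuple(dataset.feature_names))

    def test_dominator_repopulates_neighbors(self, tiny_dataset):
        env, codes, labels = _env_setup(tiny_dataset)
        strong = clf(1.0, 1, "g1")
        weak = [
            Classifier(
                tree=Constant(float(i)),
                rule=MulticlassRule(("a", "b"), (0.0,), (False,)),
                fitness=FitnessRecord(0.3, 5),
            )
            for i in range(16)
        ]
        cells = [[weak[r * 4 + c] for c in range(4)] for r in range(4)]
        cells[1][1] = strong
        grid = SolutionGrid(cells)
        cfg = EvolutionConfig(grid_dimension=4, generations=1)
        rng = np.random.default_rng(0)
        new, offspring = tournament_step(
            grid, self._blocks(tiny_dataset), env, codes, labels, cfg, rng
        )
        assert new[1, 1] is strong  # dominator persists
        for nr, nc in neighborhood(grid, 1, 1):
            assert new[nr, nc] is not grid[nr, nc]  # all 8 replaced
        assert len(offspring) == 8

    def test_identical_fitness_grid_is_noop(self, tiny_dataset):
        env, codes, labels = _env_setup(tiny_dataset)
        cells = [[clf(0.5, 3) for _ in range(4)] for _ in range(4)]
        grid = SolutionGrid(cells)
        cfg = EvolutionConfig(grid_dimension=4, generations=1)
        new, offspring = tournament_step(
            grid, self._blocks(tiny_dataset), env, codes, labels, cfg,
            np.random.default_rng(0),
        )
        assert offspring == []
        for r in range(4):
            for c in range(4):
                assert new[r, c] is grid[r, c]

    def test_same_seed_same_successor(self, tiny_dataset):
        env, codes, labels = _env_setup(tiny_dataset)
        cfg = EvolutionConfig(grid_dimension=5, generations=1)
        blocks = self._blocks(tiny_dataset)

        def one(seed):
            rng = np.random.default_rng(seed)
            grid, _ = evolve(tiny_dataset, cfg, np.random.default_rng(99),
                             blocks=blocks)
            new, _ = tournament_step(grid, blocks, env, codes, labels, cfg, rng)
            return [[c.expression for c in row] for row in new.cells]

        assert one(7) == one(7)


class TestArchive:
    def test_monotone_and_front_only(self):
        rng = np.random.default_rng(1)
        archive = ParetoArchive(cap=500)
        best_so_far = 0.0
        for _ in range(300):
            archive.add(clf(float(rng.random()), int(rng.integers(1, 20))))
            members = archive.members
            best = max(m.fitness.accuracy for m in members)
            assert best >= best_so_far
            best_so_far = best
            for a in members:
                for b in members:
                    if a is not b:
                        assert not dominates(a.fitness, b.fitness)

    def test_cap_preserves_extremes(self):
        archive = ParetoArchive(cap=10)
        # strictly improving accuracy with increasing complexity: a pure front
        for i in range(50):
            archive.add(clf(i / 50.0, i + 1))
        assert len(archive) == 10
        accs = sorted(m.fitness.accuracy for m in archive.members)
        assert accs[0] == 0.0 and accs[-1] == 49 / 50.0


class TestEvolve:
    def test_perfect_feature_reached(self, tiny_dataset):
        cfg = EvolutionConfig(grid_dimension=10, generations=200,
                              max_initial_depth=3, expert_k=0)
        _, archive = evolve(tiny_dataset, cfg, np.random.default_rng(12))
        assert archive.best_accuracy == 1.0
        # complexity-1 perfect classifier on the separating feature
        simple = [
            m for m in archive.members
            if m.fitness.complexity == 1 and m.fitness.accuracy == 1.0
        ]
        assert simple and simple[0].feature_set == {"g1"}

    def test_generation_count_contract(self, tiny_dataset):
        with pytest.raises(ValueError):
            EvolutionConfig(grid_dimension=4, generations=0)

    def test_determinism(self, tiny_dataset):
        cfg = EvolutionConfig(grid_dimension=5, generations=20, expert_k=0)

        def run(seed):
            _, archive = evolve(tiny_dataset, cfg, np.random.default_rng(seed))
            return sorted(
                (m.expression, m.fitness.accuracy, m.fitness.complexity)
                for m in archive.members
            )

        assert run(3) == run(3)
        # archive accuracies are reproducible bit-for-bit
        a, b = run(3), run(3)
        assert all(x[1] == y[1] for x, y in zip(a, b))

    def test_degenerate_dataset_rejected(self):
        d = LabeledDataset(
            np.zeros((3, 2)), ["f1", "f2"], ["a", "a", "b"]
        )
        cfg = EvolutionConfig(grid_dimension=3, generations=1)
        with pytest.raises(ValueError):
            evolve(d, cfg, np.random.default_rng(0))


class TestRunLevels:
    def test_single_level_matches_evolve(self, tiny_dataset):
        cfg = EvolutionConfig(grid_dimension=5, generations=10, expert_k=0)
        archives = run_levels(tiny_dataset, cfg, np.random.default_rng(4))
        _, direct = evolve(tiny_dataset, cfg, np.random.default_rng(4))
        assert len(archives) == 1
        assert sorted(m.expression for m in archives[0].members) == sorted(
            m.expression for m in direct.members
        )

    def test_levels_never_regress(self, tiny_dataset):
        cfg = EvolutionConfig(grid_dimension=5, generations=15, expert_k=0,
                              pareto_levels=3)
        archives = run_levels(tiny_dataset, cfg, np.random.default_rng(8))
        bests = [a.best_accuracy for a in archives]
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))
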