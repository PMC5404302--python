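"""Expression-engine contracts: protected evaluation, building-block
counting, generation, mutation, recombination, and serialization."""

import numpy as np
import pytest

from mces.expressions import (
    BuildingBlockSet,
    Constant,
    Feature,
    MutationRates,
    Operation,
    count_building_blocks,
    evaluate_expression,
    iter_nodes,
    mutate,
    parse_tree,
    random_tree,
    recombine,
    tree_to_string,
    validate_tree,
)


def t(expr: str):
    return parse_tree(expr)


class TestEvaluate:
    @pytest.mark.parametrize(
        "expr, sample, expected",
        [
            ("(x1 + x2)", {"x1": 1, "x2": 2}, 3.0),
            ("x3", {"x3": 0.7}, 0.7),
            ("(x1 / x2)", {"x1": 5, "x2": 0}, 1.0),  # protected division
            ("(x1 - x2)", {"x1": 1, "x2": 4}, -3.0),
            ("((x1 + x2) * 2.5)", {"x1": 1, "x2": 2}, 7.5),
        ],
    )
    def test_examples(self, expr, sample, expected):
        assert evaluate_expression(t(expr), sample) == pytest.approx(expected)

    def test_missing_feature_names_the_feature(self):
        with pytest.raises(KeyError, match="x9"):
            evaluate_expression(t("(x1 + x9)"), {"x1": 1.0})

    def test_vectorized_matches_scalar(self, rng):
        tree = t("((x1 * x2) - (x1 / x2))")
        x1 = rng.normal(size=20)
        x2 = rng.normal(size=20)
        vec = evaluate_expression(tree, {"x1": x1, "x2": x2})
        scalars = [
            evaluate_expression(tree, {"x1": a, "x2": b}) for a, b in zip(x1, x2)
        ]
        np.testing.assert_array_equal(vec, np.asarray(scalars))

    def test_deterministic_bit_identical(self, rng):
        tree = t("((x1 / x2) * (x2 - 3.7))")
        sample = {"x1": 1.2345678901234567, "x2": 9.87654321e-5}
        a = evaluate_expression(tree, sample)
        b = evaluate_expression(tree, sample)
        assert float(a) == float(b)

    def test_protected_evaluation_always_finite(self, blocks, rng):
        # random trees on extreme feature values never produce non-finite output
        for _ in range(1000):
            tree = random_tree(blocks, max_depth=5, rng=rng)
            sample = {
                f: float(rng.uniform(-1e6, 1e6)) for f in blocks.feature_names
            }
            assert np.isfinite(evaluate_expression(tree, sample))


class TestCount:
    @pytest.mark.parametrize(
        "expr, expected",
        [("x1", 1), ("(x1 + x2)", 3), ("((x1 + x2) * 2.5)", 5)],
    )
    def test_node_counts(self, expr, expected):
        assert count_building_blocks(t(expr)) == expected


class TestRandomTree:
    def test_depth_one_is_a_leaf(self, blocks, rng):
        for _ in range(50):
            tree = random_tree(blocks, 1, rng)
            assert isinstance(tree, (Feature, Constant))

    def test_same_seed_same_tree(self, blocks):
        a = random_tree(blocks, 4, np.random.default_rng(5))
        b = random_tree(blocks, 4, np.random.default_rng(5))
        assert a == b

    def test_depth_bounded(self, blocks, rng):
        for _ in range(1000):
            tree = random_tree(blocks, 4, rng)
            assert tree.depth() <= 4
            validate_tree(tree, blocks.feature_names)

    def test_invalid_depth(self, blocks, rng):
        with pytest.raises(ValueError):
            random_tree(blocks, 0, rng)

    def test_expert_bias_prefers_subset(self, rng):
        biased = BuildingBlockSet(
            feature_names=tuple(f"g{i}" for i in range(50)),
            preferred_features=("g0", "g1"),
            preference_bias=1.0,
            constant_probability=0.0,
        )
        for _ in range(100):
            tree = random_tree(biased, 3, rng)
            assert tree.features() <= {"g0", "g1"}


class TestMutate:
    rates_add = MutationRates(add=1.0, remove=0.0, swap=0.0)
    rates_remove = MutationRates(add=0.0, remove=1.0, swap=0.0)
    rates_swap = MutationRates(add=0.0, remove=0.0, swap=1.0)

    def test_add_grows(self, blocks, rng):
        for _ in range(100):
            tree = random_tree(blocks, 4, rng)
            child = mutate(tree, blocks, self.rates_add, rng)
            assert count_building_blocks(child) > count_building_blocks(tree)
            validate_tree(child, blocks.feature_names)

    def test_remove_shrinks_with_floor(self, blocks, rng):
        leaf = t("x1")
        assert mutate(leaf, blocks, self.rates_remove, rng) == leaf
        for _ in range(100):
            tree = random_tree(blocks, 4, rng)
            child = mutate(tree, blocks, self.rates_remove, rng)
            if count_building_blocks(tree) > 1:
                assert count_building_blocks(child) < count_building_blocks(tree)
            assert count_building_blocks(child) >= 1

    def test_swap_preserves_size(self, blocks, rng):
        for _ in range(1000):
            tree = random_tree(blocks, 4, rng)
            child = mutate(tree, blocks, self.rates_swap, rng)
            assert count_building_blocks(child) == count_building_blocks(tree)
            validate_tree(child, blocks.feature_names)

    def test_swap_leaf_stays_single_node(self, blocks, rng):
        child = mutate(t("x1"), blocks, self.rates_swap, rng)
        assert count_building_blocks(child) == 1

    def test_input_not_modified(self, blocks, rng):
        tree = t("((x1 + x2) * x3)")
        snapshot = tree_to_string(tree)
        for _ in range(50):
            mutate(tree, blocks, MutationRates(), rng)
        assert tree_to_string(tree) == snapshot

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            MutationRates(add=0.7, remove=0.7, swap=0.2)
        with pytest.raises(ValueError):
            MutationRates(add=-0.1, remove=0.0, swap=0.0)


class TestRecombine:
    def test_leaf_parents_give_a_parent_leaf(self, rng):
        child = recombine(t("x1"), t("x2"), rng)
        assert child in (t("x1"), t("x2"))

    def test_leaf_provenance(self, blocks, rng):
        a, b = t("(x1 + x2)"), t("(x3 * x4)")
        allowed = {"x1", "x2", "x3", "x4"}
        for _ in range(100):
            child = recombine(a, b, rng)
            validate_tree(child, blocks.feature_names)
            for node, _ in iter_nodes(child):
                if isinstance(node, Feature):
                    assert node.name in allowed

    def test_material_from_both_parents(self, blocks, rng):
        a, b = t("(x1 + x2)"), t("(x3 * x4)")
        for _ in range(100):
            child = recombine(a, b, rng)
            feats = child.features()
            assert feats & {"x1", "x2"}
            assert feats & {"x3", "x4"}

    def test_deterministic_under_seed(self, blocks):
        a, b = t("((x1 + x2) - x3)"), t("(x4 / 2.0)")
        c1 = recombine(a, b, np.random.default_rng(9))
        c2 = recombine(a, b, np.random.default_rng(9))
        assert c1 == c2

    def test_parents_unmodified(self, rng):
        a, b = t("(x1 + x2)"), t("(x3 * x4)")
        sa, sb = tree_to_string(a), tree_to_string(b)
        for _ in range(20):
            recombine(a, b, rng)
        assert tree_to_string(a) == sa and tree_to_string(b) == sb


class TestSerialization:
    def test_round_trip_lossless(self, blocks, rng):
        for _ in range(500):
            tree = random_tree(blocks, 5, rng)
            assert parse_tree(tree_to_string(tree)) == tree

    def test_example_format(self):
        tree = Operation(
            "*", (Operation("+", (Feature("Gsg1"), Constant(2.5))), Feature("Stip1"))
        )
        assert tree_to_string(tree) == "((Gsg1 + 2.5) * Stip1)"

    @pytest.mark.parametrize("bad", ["(x1 +", "x1 x2", "()", "(x1 ? x2)"])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_tree(bad)
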