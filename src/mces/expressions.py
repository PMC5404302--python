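"""Symbolic discriminant expression trees and their genetic operators.

An expression tree is the evolving half of a classifier: a composition of
building blocks (feature references, real constants, arithmetic operators)
whose scalar output per sample is thresholded by the multi-class rule. The
number of building blocks — i.e. the total node count — is the model
complexity objective of the Pareto fitness.

Evaluation is *protected*: division by a near-zero denominator yields 1.0,
and every operator output is clamped into [-1e12, 1e12] (NaN maps to 0.0),
so any tree over finite inputs produces finite values. Evaluation is
vectorized: feature values may be scalars or aligned numpy arrays.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BuildingBlockSet",
    "MutationRates",
    "Node",
    "Feature",
    "Constant",
    "Operation",
    "evaluate_expression",
    "count_building_blocks",
    "random_tree",
    "mutate",
    "recombine",
    "tree_to_string",
    "parse_tree",
    "validate_tree",
]

#: Output magnitude bound guaranteeing finiteness under composition.
CLAMP = 1.0e12
#: Denominator magnitude below which protected division returns 1.0.
DIV_EPS = 1.0e-9

OPERATORS: tuple[str, ...] = ("+", "-", "*", "/")
OPERATOR_ARITY: dict[str, int] = {op: 2 for op in OPERATORS}

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.:\-]*$")


def _protect(values):
    """Clamp non-finite and oversized results into the protected range."""
    values = np.nan_to_num(values, nan=0.0, posinf=CLAMP, neginf=-CLAMP)
    return np.clip(values, -CLAMP, CLAMP)


# ---------------------------------------------------------------------------
# Nodes
# ---------------------------------------------------------------------------


class Node:
    """Base class for expression-tree nodes. Nodes are immutable."""

    __slots__ = ()

    def evaluate(self, env: Mapping[str, object]):
        raise NotImplementedError

    def size(self) -> int:
        raise NotImplementedError

    def depth(self) -> int:
        raise NotImplementedError

    def children(self) -> tuple["Node", ...]:
        return ()

    def features(self) -> set[str]:
        out: set[str] = set()
        for node, _ in iter_nodes(self):
            if isinstance(node, Feature):
                out.add(node.name)
        return out


@dataclass(frozen=True, slots=True)
class Feature(Node):
    name: str

    def evaluate(self, env):
        try:
            return np.asarray(env[self.name], dtype=float)
        except KeyError:
            raise KeyError(
                f"feature '{self.name}' not present in the sample/environment"
            ) from None

    def size(self) -> int:
        return 1

    def depth(self) -> int:
        return 1


@dataclass(frozen=True, slots=True)
class Constant(Node):
    value: float

    def evaluate(self, env):
        return np.float64(self.value)

    def size(self) -> int:
        return 1

    def depth(self) -> int:
        return 1


@dataclass(frozen=True, slots=True)
class Operation(Node):
    symbol: str
    operands: tuple[Node, ...]

    def __post_init__(self):
        if self.symbol not in OPERATOR_ARITY:
            raise ValueError(f"unknown operator '{self.symbol}'")
        if len(self.operands) != OPERATOR_ARITY[self.symbol]:
            raise ValueError(
                f"operator '{self.symbol}' expects {OPERATOR_ARITY[self.symbol]}"
                f" operands, got {len(self.operands)}"
            )

    def evaluate(self, env):
        a = self.operands[0].evaluate(env)
        b = self.operands[1].evaluate(env)
        if self.symbol == "+":
            out = a + b
        elif self.symbol == "-":
            out = a - b
        elif self.symbol == "*":
            out = a * b
        else:  # protected division
            b_arr = np.asarray(b, dtype=float)
            near_zero = np.abs(b_arr) < DIV_EPS
            safe = np.where(near_zero, 1.0, b_arr)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                out = np.where(near_zero, 1.0, a / safe)
        with np.errstate(over="ignore", invalid="ignore"):
            return _protect(out)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.operands)

    def depth(self) -> int:
        return 1 + max(c.depth() for c in self.operands)

    def children(self) -> tuple[Node, ...]:
        return self.operands


# ---------------------------------------------------------------------------
# Building blocks and mutation rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BuildingBlockSet:
    """The vocabulary a tree is built from.

    ``preferred_features``/``preference_bias`` implement expert-knowledge
    biasing: feature leaves are drawn from the preferred subset with the
    given probability and from all features otherwise.
    """

    feature_names: tuple[str, ...]
    operators: tuple[str, ...] = OPERATORS
    constant_range: tuple[float, float] = (-10.0, 10.0)
    preferred_features: tuple[str, ...] | None = None
    preference_bias: float = 0.8
    constant_probability: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "operators", tuple(self.operators))
        if not self.feature_names:
            raise ValueError("feature_names must be non-empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if not self.operators:
            raise ValueError("operators must be non-empty")
        unknown = [op for op in self.operators if op not in OPERATOR_ARITY]
        if unknown:
            raise ValueError(f"unsupported operators: {unknown}")
        lo, hi = self.constant_range
        if lo > hi:
            raise ValueError("constant_range lower bound exceeds upper bound")
        if self.preferred_features is not None:
            object.__setattr__(
                self, "preferred_features", tuple(self.preferred_features)
            )
            missing = set(self.preferred_features) - set(self.feature_names)
            if missing:
                raise ValueError(
                    f"preferred features not in feature_names: {sorted(missing)[:5]}"
                )
        if not 0.0 <= self.preference_bias <= 1.0:
            raise ValueError("preference_bias must be in [0, 1]")

    def random_feature(self, rng: np.random.Generator) -> Feature:
        pool = self.feature_names
        if self.preferred_features and rng.random() < self.preference_bias:
            pool = self.preferred_features
        return Feature(pool[int(rng.integers(len(pool)))])

    def random_constant(self, rng: np.random.Generator) -> Constant:
        lo, hi = self.constant_range
        return Constant(float(rng.uniform(lo, hi)))

    def random_leaf(self, rng: np.random.Generator) -> Node:
        if rng.random() < self.constant_probability:
            return self.random_constant(rng)
        return self.random_feature(rng)

    def random_operator(self, rng: np.random.Generator) -> str:
        return self.operators[int(rng.integers(len(self.operators)))]


@dataclass(frozen=True)
class MutationRates:
    """Probabilities of the three structural mutations; remainder is a no-op."""

    add: float = 0.25
    remove: float = 0.25
    swap: float = 0.5

    def __post_init__(self):
        for name, p in (("add", self.add), ("remove", self.remove), ("swap", self.swap)):
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ValueError(f"mutation rate '{name}' must be in [0, 1]")
        if self.add + self.remove + self.swap > 1.0 + 1e-12:
            raise ValueError("mutation rates must sum to at most 1")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def evaluate_expression(tree: Node, sample: Mapping[str, object]):
    """Evaluate ``tree`` on a sample (feature -> value) or a column
    environment (feature -> aligned array). Output is guaranteed finite."""
    return tree.evaluate(sample)


def count_building_blocks(tree: Node) -> int:
    """Total node count: features + constants + operators."""
    return tree.size()


def iter_nodes(tree: Node) -> Iterator[tuple[Node, tuple[int, ...]]]:
    """Preorder traversal yielding (node, path); path = child indices from root."""
    stack: list[tuple[Node, tuple[int, ...]]] = [(tree, ())]
    while stack:
        node, path = stack.pop()
        yield node, path
        for i, child in reversed(list(enumerate(node.children()))):
            stack.append((child, path + (i,)))


def subtree_at(tree: Node, path: tuple[int, ...]) -> Node:
    node = tree
    for i in path:
        node = node.children()[i]
    return node


def replace_subtree(tree: Node, path: tuple[int, ...], new: Node) -> Node:
    """Return a copy of ``tree`` with the subtree at ``path`` replaced."""
    if not path:
        return new
    if not isinstance(tree, Operation):
        raise ValueError("path descends below a leaf")
    i, rest = path[0], path[1:]
    operands = list(tree.operands)
    operands[i] = replace_subtree(operands[i], rest, new)
    return Operation(tree.symbol, tuple(operands))


def random_tree(
    blocks: BuildingBlockSet, max_depth: int, rng: np.random.Generator
) -> Node:
    """Grow-style random tree of depth ≤ max_depth.

    The leaf probability rises linearly with depth so the initial population
    spans a range of sizes; depth-1 calls always return a single leaf.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")

    def grow(remaining: int) -> Node:
        if remaining <= 1:
            return blocks.random_leaf(rng)
        p_leaf = 1.0 - remaining / max_depth
        if rng.random() < p_leaf:
            return blocks.random_leaf(rng)
        symbol = blocks.random_operator(rng)
        arity = OPERATOR_ARITY[symbol]
        return Operation(symbol, tuple(grow(remaining - 1) for _ in range(arity)))

    return grow(max_depth)


def _pick_node(tree: Node, rng: np.random.Generator, internal_only=False,
               exclude_root=False) -> tuple[int, ...] | None:
    paths = [p for n, p in iter_nodes(tree)
             if not internal_only or isinstance(n, Operation)]
    if exclude_root:
        paths = [p for p in paths if p != ()]
    if not paths:
        return None
    return paths[int(rng.integers(len(paths)))]


def mutate(
    tree: Node,
    blocks: BuildingBlockSet,
    rates: MutationRates,
    rng: np.random.Generator,
) -> Node:
    """Apply one structural mutation (add / remove / swap a building block).

    add    wraps a random subtree in a new operator with a fresh leaf sibling
           (node count +2);
    remove hoists a random child over its parent (count shrinks, floor 1);
    swap   replaces a random leaf with a fresh leaf, or a random operator
           symbol with another (count unchanged).
    With probability 1 - add - remove - swap the tree is returned unchanged.
    """
    if not isinstance(rates, MutationRates):
        rates = MutationRates(*rates)
    u = rng.random()
    if u < rates.add:
        path = _pick_node(tree, rng)
        target = subtree_at(tree, path)
        symbol = blocks.random_operator(rng)
        leaf = blocks.random_leaf(rng)
        pair = (target, leaf) if rng.random() < 0.5 else (leaf, target)
        return replace_subtree(tree, path, Operation(symbol, pair))
    if u < rates.add + rates.remove:
        path = _pick_node(tree, rng, internal_only=True)
        if path is None:  # single leaf: cannot shrink below one node
            return tree
        node = subtree_at(tree, path)
        keep = node.children()[int(rng.integers(len(node.children())))]
        return replace_subtree(tree, path, keep)
    if u < rates.add + rates.remove + rates.swap:
        path = _pick_node(tree, rng)
        node = subtree_at(tree, path)
        if isinstance(node, Operation):
            symbol = blocks.random_operator(rng)
            return replace_subtree(tree, path, Operation(symbol, node.operands))
        return replace_subtree(tree, path, blocks.random_leaf(rng))
    return tree


def recombine(a: Node, b: Node, rng: np.random.Generator) -> Node:
    """Subtree crossover: a random subtree of ``a`` (never the root when
    ``a`` has more than one node) is replaced by a random subtree of ``b``.

    When both parents have more than one node the offspring therefore
    contains material from each. Parents are not modified.
    """
    cut = _pick_node(a, rng, exclude_root=a.size() > 1)
    if cut is None:
        cut = ()
    graft_path = _pick_node(b, rng)
    graft = subtree_at(b, graft_path)
    return replace_subtree(a, cut, graft)


# ---------------------------------------------------------------------------
# Serialization: parenthesized infix, lossless round-trip
# ---------------------------------------------------------------------------


def tree_to_string(tree: Node) -> str:
    """Serialize to parenthesized infix, e.g. ``((Gsg1 + 2.5) * Stip1)``.

    Constants print via ``repr(float)`` (shortest round-tripping form), so
    parsing the string reconstructs a structurally identical tree.
    """
    if isinstance(tree, Feature):
        if not _NAME_RE.match(tree.name):
            raise ValueError(
                f"feature name {tree.name!r} is not serializable "
                "(must start with a letter/underscore)"
            )
        return tree.name
    if isinstance(tree, Constant):
        return repr(float(tree.value))
    parts = [tree_to_string(c) for c in tree.operands]
    return f"({parts[0]} {tree.symbol} {parts[1]})"


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_tree(text: str) -> Node:
    """Parse the infix form produced by :func:`tree_to_string`."""
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def error(msg: str):
        raise ValueError(f"cannot parse expression at token {pos}: {msg}")

    def parse() -> Node:
        nonlocal pos
        if pos >= len(tokens):
            error("unexpected end of input")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            left = parse()
            if pos >= len(tokens) or tokens[pos] not in OPERATOR_ARITY:
                error("expected operator")
            symbol = tokens[pos]
            pos += 1
            right = parse()
            if pos >= len(tokens) or tokens[pos] != ")":
                error("expected ')'")
            pos += 1
            return Operation(symbol, (left, right))
        if tok == ")":
            error("unexpected ')'")
        if _NAME_RE.match(tok):
            return Feature(tok)
        try:
            return Constant(float(tok))
        except ValueError:
            error(f"token {tok!r} is neither a feature name nor a number")

    tree = parse()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens after expression: {tokens[pos:]}")
    return tree


def validate_tree(tree: Node, feature_names: Sequence[str] | None = None) -> None:
    """Structural validator: raises ValueError on any invariant violation."""
    allowed = set(feature_names) if feature_names is not None else None
    count = 0
    for node, _ in iter_nodes(tree):
        count += 1
        if isinstance(node, Operation):
            if node.symbol not in OPERATOR_ARITY:
                raise ValueError(f"unknown operator {node.symbol!r}")
            if len(node.operands) != OPERATOR_ARITY[node.symbol]:
                raise ValueError("operand count does not match operator arity")
        elif isinstance(node, Constant):
            if not math.isfinite(node.value):
                raise ValueError("non-finite constant in tree")
        elif isinstance(node, Feature):
            if allowed is not None and node.name not in allowed:
                raise ValueError(f"tree references unknown feature {node.name!r}")
        else:
            raise ValueError(f"unknown node type {type(node).__name__}")
    if count < 1:
        raise ValueError("empty tree")
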