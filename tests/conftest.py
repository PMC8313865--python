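"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: random
trees are built as newick strings, bipartitions are enumerated from leaf
subsets, triple topologies are read off pruned three-leaf trees, and
hypergeometric tails are summed with integer combinatorics.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import dendropy
import numpy as np
import pytest

from strlineage.simulate import make_panel
from strlineage.stutter import SlippageParams, StutterModel


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(20, seed=123)


class ConstantSlipModel(StutterModel):
    """Stutter model with length-independent slip probabilities."""

    def __init__(self, cycles: int, down: float, up: float):
        super().__init__(cycles=cycles)
        self._down = down
        self._up = up

    def slip_down(self, unit, length):
        return 0.0 if length <= 1 else self._down

    def slip_up(self, unit, length):
        return self._up


# ---------------------------------------------------------------------------
# random rooted/unrooted trees as newick strings
# ---------------------------------------------------------------------------

def random_binary_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary topology over the given labels."""

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        picks = list(rng.permutation(len(items)))
        left = [items[i] for i in picks[:k]]
        right = [items[i] for i in picks[k:]]
        return f"({build(left)},{build(right)})"

    return build(list(labels)) + ";"


def tree_from_newick(newick: str, rooted: bool = True) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = rooted
    return t


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_tree_sides(tree: dendropy.Tree) -> list[frozenset]:
    """All edge-induced leaf sides of a tree, via newick-level traversal."""
    sides = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        sides.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return sides


def oracle_transfer_distance(side: frozenset, tree: dendropy.Tree) -> int:
    """Min bipartition Hamming distance by exhaustive enumeration."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    best = None
    for other in oracle_tree_sides(tree):
        h = len(side ^ other)
        d = min(h, len(leaves) - h)
        best = d if best is None else min(best, d)
    return best


def oracle_tbe(side: frozenset, replicates, n_leaves: int) -> float:
    p = min(len(side), n_leaves - len(side))
    deltas = [oracle_transfer_distance(side, t) for t in replicates]
    return 1.0 - (sum(deltas) / len(deltas)) / (p - 1)


def oracle_triple_topology(tree: dendropy.Tree, triple: tuple[str, str, str]):
    """Induced rooted topology of a leaf triple, via subtree extraction.

    Returns the cherry pair as a frozenset, or None for an unresolved
    triple.
    """
    sub = tree.extract_tree_with_taxa_labels(list(triple))
    sub.suppress_unifurcations()
    root_children = sub.seed_node.child_nodes()
    if len(root_children) != 2:
        return None
    for child in root_children:
        leaves = [l.taxon.label for l in child.leaf_iter()]
        if len(leaves) == 2:
            return frozenset(leaves)
    return None


def oracle_triples_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    labels = sorted(l.taxon.label for l in t1.leaf_node_iter())
    total = 0
    differ = 0
    for triple in combinations(labels, 3):
        total += 1
        if oracle_triple_topology(t1, triple) != oracle_triple_topology(t2, triple):
            differ += 1
    return differ / total


def oracle_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    return sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / comb(N, n)
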