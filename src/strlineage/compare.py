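"""Rooted-tree comparison by normalized triples distance, and the
coverage-subsampling analysis built on it.

The triples distance between two rooted trees over the same leaves is the
fraction of leaf triples {a, b, c} whose induced rooted topology (which of
the three pairs coalesces most recently, or none for a polytomy) differs
between the trees.  By default a triple that is resolved in one tree and
unresolved in the other counts as differing; a flag restricts the count to
triples resolved in both trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phylo import LineageTree, leaf_labels

# triple topology codes: 0 => (a,b) cherry, 1 => (a,c), 2 => (b,c),
# 3 => unresolved
UNRESOLVED = 3


def _lca_depths(tree: LineageTree, order: list[str]) -> np.ndarray:
    """Pairwise LCA depths (edges from the root) for the given leaf order."""
    index = {name: i for i, name in enumerate(order)}
    n = len(order)
    depth = np.zeros((n, n), dtype=np.int64)

    node_depth: dict[int, int] = {id(tree.seed_node): 0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        node_depth[id(node)] = node_depth[id(node.parent_node)] + 1

    leaves_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaves_below[id(node)] = [index[node.taxon.label]]
            continue
        children = [leaves_below[id(c)] for c in node.child_nodes()]
        d = node_depth[id(node)]
        for i, a in enumerate(children):
            for b in children[i + 1 :]:
                for x in a:
                    for y in b:
                        depth[x, y] = depth[y, x] = d
        merged = [x for group in children for x in group]
        leaves_below[id(node)] = merged
    return depth


def _triple_codes(depth: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Topology code per triple from a pairwise LCA depth matrix."""
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    dab = depth[a, b]
    dac = depth[a, c]
    dbc = depth[b, c]
    stacked = np.stack([dab, dac, dbc])
    top = stacked.max(axis=0)
    is_top = stacked == top[None, :]
    n_top = is_top.sum(axis=0)
    codes = np.full(triples.shape[0], UNRESOLVED, dtype=np.int64)
    unique = n_top == 1
    codes[unique] = is_top[:, unique].argmax(axis=0)
    return codes


def triples_distance(
    t1: LineageTree, t2: LineageTree, resolved_only: bool = False
) -> float:
    """Normalized triples distance between two rooted trees.

    Both trees must be rooted and share the same leaf set (no pruning).
    With ``resolved_only`` the distance is normalized over triples resolved
    in both trees; otherwise over all C(n, 3) triples, counting
    resolved-vs-unresolved as a difference.
    """
    for t in (t1, t2):
        if not t.is_rooted:
            raise ValueError("triples distance requires rooted trees")
    order = sorted(leaf_labels(t1))
    if sorted(leaf_labels(t2)) != order:
        raise ValueError("trees have different leaf sets")
    n = len(order)
    if n < 3:
        return 0.0
    d1 = _lca_depths(t1, order)
    d2 = _lca_depths(t2, order)
    triples = np.array(list(combinations(range(n), 3)), dtype=np.int64)
    c1 = _triple_codes(d1, triples)
    c2 = _triple_codes(d2, triples)
    if resolved_only:
        both = (c1 != UNRESOLVED) & (c2 != UNRESOLVED)
        if not both.any():
            return 0.0
        return float((c1[both] != c2[both]).mean())
    return float((c1 != c2).mean())


# ---------------------------------------------------------------------------
# Coverage curve
# ---------------------------------------------------------------------------

@dataclass
class CoveragePoint:
    coverage: int
    mean_distance: float
    sd_distance: float
    n_runs: int


def coverage_curve(
    dataset,
    coverages: list[int],
    n_runs_per_point: int = 3,
    seed: np.random.Generator | int | None = None,
    caller=None,
    root_group: list[str] | None = None,
    min_shared: int | None = None,
) -> pd.DataFrame:
    """Tree stability against the full-coverage reconstruction as coverage
    is computationally subsampled.

    For each target coverage the histograms are downsampled without
    replacement, re-genotyped and re-reconstructed, and the triples
    distance to the tree built from full data is recorded (mean +/- sd over
    ``n_runs_per_point`` subsampling draws).
    """
    from .genotype import GenotypeCaller, assemble_matrix, call_histograms
    from .phylo import build_nj_tree, mutation_count_distance, root_tree
    from .readmap import subsample_histograms
    from .simulate import reference_genotype

    rng = np.random.default_rng(seed)
    if caller is None:
        caller = GenotypeCaller(dataset.stutter)
    units = {l.locus_id: l.unit for l in dataset.loci}
    cells = dataset.true_genotypes.index.tolist()
    if min_shared is None:
        min_shared = min(50, max(1, len(dataset.loci) // 4))
    founder = reference_genotype(dataset.loci, diploid=dataset.diploid)

    def reconstruct(histograms):
        calls = call_histograms(histograms, caller, units)
        matrix, _ = assemble_matrix(calls, cells=cells)
        dm = mutation_count_distance(matrix, min_shared=min_shared)
        tree = build_nj_tree(dm)
        return root_tree(
            tree, matrix, genotype=founder, dm=dm, min_shared=min_shared
        )

    full_tree = reconstruct(dataset.histograms)
    rows = []
    for coverage in coverages:
        distances = []
        for _ in range(n_runs_per_point):
            sub = subsample_histograms(
                dataset.histograms, target_coverage=coverage, seed=rng
            )
            distances.append(triples_distance(reconstruct(sub), full_tree))
        rows.append(
            CoveragePoint(
                coverage=coverage,
                mean_distance=float(np.mean(distances)),
                sd_distance=float(np.std(distances, ddof=1))
                if len(distances) > 1
                else 0.0,
                n_runs=len(distances),
            )
        )
    return pd.DataFrame(
        [
            {
                "coverage": p.coverage,
                "mean_distance": p.mean_distance,
                "sd_distance": p.sd_distance,
                "n_runs": p.n_runs,
            }
            for p in rows
        ]
    )
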