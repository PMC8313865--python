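"""Mutation-count distances, neighbor-joining reconstruction, and rooting.

The pairwise distance between two cells is the number of shared genotyped
pseudo-loci at which their repeat counts differ, optionally normalized by
the number of shared loci (the default).  Trees are reconstructed with
neighbor joining on that matrix; a PHYLIP exporter is provided so the same
matrix can be fed to external distance-based tools (e.g. FastTree2).
Rooting uses the median genotype of a designated outgroup population,
either by projecting it onto the closest edge of the unrooted tree or by
re-running the reconstruction with the median genotype as a synthetic
outgroup taxon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

DEFAULT_MIN_SHARED = 50

LineageTree = dendropy.Tree  # alias: trees are dendropy trees throughout


class DistanceError(ValueError):
    """Raised when pairwise distances cannot be defined."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray          # symmetric, zero diagonal; NaN = undefined
    shared: np.ndarray          # per-pair shared genotyped pseudo-loci
    normalized: bool = True

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.as_dataframe().to_csv(path, sep="\t", index_label="cell_id")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance matrix (for external tree builders)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name}  {row}\n")


def mutation_count_distance(
    matrix: pd.DataFrame,
    normalize: bool = True,
    min_shared: int = DEFAULT_MIN_SHARED,
    require_defined: bool = True,
) -> DistanceMatrix:
    """Pairwise mutation-count distances over a cells x pseudo-loci matrix.

    raw(i, j) = #{loci genotyped in both with differing repeat counts};
    normalized(i, j) = raw / #shared.  Pairs sharing fewer than
    ``min_shared`` loci are undefined (NaN); with ``require_defined`` such
    pairs raise :class:`DistanceError` listing the offenders.
    """
    if matrix.shape[0] < 2:
        raise DistanceError("need at least two cells")
    ids = [str(i) for i in matrix.index]
    x = matrix.to_numpy(dtype=float)
    valid = np.isfinite(x)
    shared = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        neq = (
            (x[:, None, :] != x[None, :, :])
            & valid[:, None, :]
            & valid[None, :, :]
        ).sum(axis=2)
    raw = neq.astype(float)
    values = raw.copy()
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(shared > 0, raw / np.maximum(shared, 1), np.nan)
    values[shared < min_shared] = np.nan
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix(
        ids=ids, values=values, shared=shared, normalized=normalize
    )
    if require_defined:
        bad = dm.undefined_pairs()
        if bad:
            raise DistanceError(
                f"{len(bad)} cell pair(s) share fewer than {min_shared} "
                f"genotyped loci: {bad[:10]}"
            )
    return dm


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def build_nj_tree(dm: DistanceMatrix) -> LineageTree:
    """Neighbor joining with deterministic lexicographic tie-breaking.

    Ties in the Q criterion are resolved by the lexicographically smallest
    pair of cluster names (a cluster is named after its smallest member).
    Negative branch lengths are clamped to zero with a warning.  Returns an
    unrooted dendropy tree (trifurcating seed node for n >= 3).
    """
    if np.isnan(dm.values).any():
        raise DistanceError("distance matrix contains undefined pairs")
    n = len(dm.ids)
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in dm.ids:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=name)
        nodes.append(node)
    if n == 1:
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node.add_child(nodes[0])
        tree.is_rooted = False
        return tree

    D = dm.values.copy().astype(float)
    active = list(range(n))
    names = {i: dm.ids[i] for i in range(n)}
    clamped = False

    def attach(parent: dendropy.Node, child_idx: int, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        child = nodes[child_idx]
        child.edge.length = length
        parent.add_child(child)

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((names[active[a]], names[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        new = dendropy.Node()
        nodes.append(new)
        k = len(nodes) - 1
        attach(new, i, li)
        attach(new, j, lj)
        # distances from the new cluster to the remaining ones
        Dk = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            Dk[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[k, : k] = Dk[:k]
        D[: k, k] = Dk[:k]
        names[k] = min(names[i], names[j])
        active = [c for c in active if c not in (i, j)] + [k]

    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    if len(active) == 2:
        i, j = active
        d = D[i, j]
        # join the final two clusters at the seed node
        if nodes[i].is_leaf() and nodes[j].is_leaf():
            attach(root, i, d / 2.0)
            attach(root, j, d / 2.0)
        else:
            # graft the smaller cluster onto the larger one's node
            big, small = (i, j) if not nodes[i].is_leaf() else (j, i)
            for child in list(nodes[big].child_nodes()):
                nodes[big].remove_child(child)
                root.add_child(child)
            attach(root, small, d)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def leaf_labels(tree: LineageTree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def edge_bipartitions(
    tree: LineageTree, include_trivial: bool = False
) -> list[tuple[frozenset, dendropy.Edge]]:
    """(leaf-set below edge, edge) for every edge; non-trivial splits have
    2 <= |side| <= n-2."""
    all_leaves = frozenset(leaf_labels(tree))
    n = len(all_leaves)
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(
            l.taxon.label for l in node.leaf_iter()
        )
        size = len(side)
        if size == 0 or size == n:
            continue
        if not include_trivial and (size < 2 or size > n - 2):
            continue
        out.append((side, node.edge))
    return out


def bipartition_set(tree: LineageTree) -> set[frozenset]:
    """Canonical non-trivial splits: each reported as the side not
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    out = set()
    for side, _edge in edge_bipartitions(tree, include_trivial=False):
        canonical = side if anchor not in side else all_leaves - side
        out.add(canonical)
    return out


# ---------------------------------------------------------------------------
# Median genotype and rooting
# ---------------------------------------------------------------------------

def median_genotype(matrix: pd.DataFrame, group: list[str]) -> pd.Series:
    """Per pseudo-locus lower median of the group's non-missing values."""
    if not group:
        raise ValueError("group must be non-empty")
    sub = matrix.loc[list(group)]

    def lower_median(col: pd.Series) -> float:
        vals = np.sort(col.dropna().to_numpy())
        if vals.size == 0:
            return np.nan
        return float(vals[(vals.size - 1) // 2])

    return sub.apply(lower_median, axis=0)


def _genotype_distance_to_rows(
    genotype: pd.Series, matrix: pd.DataFrame, normalized: bool
) -> pd.Series:
    g = genotype.reindex(matrix.columns).to_numpy(dtype=float)
    x = matrix.to_numpy(dtype=float)
    both = np.isfinite(g)[None, :] & np.isfinite(x)
    with np.errstate(invalid="ignore"):
        neq = ((x != g[None, :]) & both).sum(axis=1).astype(float)
    shared = both.sum(axis=1)
    if normalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            neq = np.where(shared > 0, neq / np.maximum(shared, 1), np.nan)
    return pd.Series(neq, index=matrix.index)


def root_tree(
    tree: LineageTree,
    matrix: pd.DataFrame,
    group: list[str] | None = None,
    genotype: pd.Series | None = None,
    mode: str = "nearest-edge",
    dm: DistanceMatrix | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> LineageTree:
    """Root a tree at (the median genotype of) an outgroup population.

    ``mode='nearest-edge'`` (default) projects the median genotype onto the
    tree: for every split (A|B) the estimated distance from the genotype to
    the path joining the two sides is mean over pairs (a in A, b in B) of
    (d(q,a) + d(q,b) - d(a,b)) / 2, and the root goes to the midpoint of the
    minimizing edge.  ``mode='outgroup'`` re-runs neighbor joining with the
    median genotype as a synthetic outgroup leaf and roots on its
    attachment edge.  Rooting is idempotent.
    """
    if genotype is None:
        if not group:
            raise ValueError("provide either group or genotype")
        genotype = median_genotype(matrix, group)
    normalized = dm.normalized if dm is not None else True

    if mode == "outgroup":
        aug = matrix.copy()
        aug.loc["__outgroup__"] = genotype.reindex(matrix.columns)
        aug_dm = mutation_count_distance(
            aug, normalize=normalized, min_shared=min_shared
        )
        aug_tree = build_nj_tree(aug_dm)
        out_leaf = next(
            l for l in aug_tree.leaf_node_iter() if l.taxon.label == "__outgroup__"
        )
        aug_tree.to_outgroup_position(out_leaf, update_bipartitions=False)
        parent = out_leaf.parent_node
        parent.remove_child(out_leaf)
        aug_tree.suppress_unifurcations()
        aug_tree.is_rooted = True
        return aug_tree

    if mode != "nearest-edge":
        raise ValueError(f"unknown rooting mode: {mode}")

    if dm is None:
        dm = mutation_count_distance(
            matrix, normalize=normalized, min_shared=min_shared
        )
    tree = tree.clone(depth=1)
    q_dist = _genotype_distance_to_rows(genotype, matrix, normalized)
    idx = {name: i for i, name in enumerate(dm.ids)}
    all_leaves = frozenset(leaf_labels(tree))

    def canonical(side: frozenset) -> frozenset:
        other = all_leaves - side
        return min(side, other, key=lambda s: tuple(sorted(s)))

    best_edge = None
    best_key = None
    for side, edge in edge_bipartitions(tree, include_trivial=True):
        other = all_leaves - side
        a_idx = [idx[l] for l in side]
        b_idx = [idx[l] for l in other]
        qa = float(np.mean([q_dist.iloc[i] for i in a_idx]))
        qb = float(np.mean([q_dist.iloc[i] for i in b_idx]))
        dab = float(np.mean(dm.values[np.ix_(a_idx, b_idx)]))
        score = 0.5 * (qa + qb - dab)
        key = (score, tuple(sorted(canonical(side))))
        if best_key is None or key < best_key:
            best_key = key
            best_edge = edge
            best_split = canonical(side)

    # idempotence: if already rooted on the chosen split, leave unchanged
    seed_children = tree.seed_node.child_nodes()
    if tree.is_rooted and len(seed_children) == 2:
        below = frozenset(l.taxon.label for l in seed_children[0].leaf_iter())
        if canonical(below) == best_split:
            return tree
    length = best_edge.length or 0.0
    tree.reroot_at_edge(
        best_edge, length1=length / 2.0, length2=length / 2.0
    )
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree
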