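"""Mutation-count distances, neighbor joining, median-genotype rooting."""

import numpy as np
import pandas as pd
import pytest

from strlineage.phylo import (
    DistanceError,
    DistanceMatrix,
    bipartition_set,
    build_nj_tree,
    leaf_labels,
    median_genotype,
    mutation_count_distance,
    root_tree,
)


def matrix_from_rows(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)


class TestMutationCountDistance:
    def test_identical_rows_zero(self):
        m = matrix_from_rows({"a": [13, 14, 15], "b": [13, 14, 15]})
        dm = mutation_count_distance(m, min_shared=1)
        assert dm.values[0, 1] == 0.0

    def test_raw_and_normalized_counts(self):
        a = [13] * 10
        b = [13] * 7 + [14, 15, 16]
        m = matrix_from_rows({"a": a, "b": b})
        raw = mutation_count_distance(m, normalize=False, min_shared=1)
        norm = mutation_count_distance(m, normalize=True, min_shared=1)
        assert raw.values[0, 1] == 3.0
        assert norm.values[0, 1] == pytest.approx(0.3)
        assert raw.shared[0, 1] == 10

    def test_missing_entries_excluded_from_shared(self):
        m = matrix_from_rows({"a": [13, 14, np.nan], "b": [13, 15, 16]})
        dm = mutation_count_distance(m, min_shared=1)
        assert dm.shared[0, 1] == 2
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_column_permutation_invariance(self, rng):
        m = matrix_from_rows(
            {c: list(rng.integers(10, 16, size=30)) for c in "abcd"}
        )
        dm1 = mutation_count_distance(m, min_shared=1)
        perm = rng.permutation(m.shape[1])
        dm2 = mutation_count_distance(m.iloc[:, perm], min_shared=1)
        np.testing.assert_allclose(dm1.values, dm2.values)

    def test_min_shared_raises_listing_pairs(self):
        m = matrix_from_rows({"a": [13, np.nan], "b": [np.nan, 14]})
        with pytest.raises(DistanceError, match=r"\('a', 'b'\)"):
            mutation_count_distance(m, min_shared=1)

    def test_single_cell_rejected(self):
        with pytest.raises(DistanceError):
            mutation_count_distance(matrix_from_rows({"a": [1, 2]}))

    def test_phylip_export(self, tmp_path):
        m = matrix_from_rows({"a": [13, 14], "b": [13, 15]})
        dm = mutation_count_distance(m, min_shared=1)
        path = tmp_path / "d.phylip"
        dm.to_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("a") and lines[2].startswith("b")


def additive_matrix_from_tree(newick_edges):
    """Distances from a known 4-taxon tree ((a,b),(c,d)) with given edges."""
    ea, eb, ec, ed, internal = newick_edges
    ids = ["a", "b", "c", "d"]
    d = np.zeros((4, 4))
    d[0, 1] = d[1, 0] = ea + eb
    d[2, 3] = d[3, 2] = ec + ed
    for i, ei in ((0, ea), (1, eb)):
        for j, ej in ((2, ec), (3, ed)):
            d[i, j] = d[j, i] = ei + ej + internal
    return DistanceMatrix(ids=ids, values=d, shared=np.full((4, 4), 100))


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_topology(self):
        dm = additive_matrix_from_tree((2.0, 3.0, 4.0, 1.0, 5.0))
        tree = build_nj_tree(dm)
        assert bipartition_set(tree) == {frozenset({"c", "d"})}

    def test_three_leaf_star_consistent_lengths(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        dm = DistanceMatrix(ids=["a", "b", "c"], values=d, shared=np.full((3, 3), 10))
        tree = build_nj_tree(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        assert lengths == pytest.approx({"a": 1.0, "b": 3.0, "c": 5.0})

    def test_row_order_invariance(self, rng):
        n = 8
        ids = [f"t{i}" for i in range(n)]
        base = rng.random((n, n)) * 5
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        dm1 = DistanceMatrix(ids=ids, values=d, shared=np.full((n, n), 100))
        perm = list(rng.permutation(n))
        dm2 = DistanceMatrix(
            ids=[ids[i] for i in perm],
            values=d[np.ix_(perm, perm)],
            shared=np.full((n, n), 100),
        )
        assert bipartition_set(build_nj_tree(dm1)) == bipartition_set(
            build_nj_tree(dm2)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_nj_on_additive_matrices(self, seed):
        """Cross-check against scikit-bio's neighbor joining on distances
        that are additive on a random binary tree."""
        skbio = pytest.importorskip("skbio")
        from conftest import random_binary_newick, tree_from_newick

        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(7)]
        ref = tree_from_newick(random_binary_newick(labels, rng))
        for edge in ref.preorder_edge_iter():
            edge.length = float(rng.uniform(0.5, 2.0))
        pdm = ref.phylogenetic_distance_matrix()
        d = np.zeros((7, 7))
        taxa = {t.label: t for t in ref.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d[i, j] = d[j, i] = pdm.distance(taxa[a], taxa[b])
        dm = DistanceMatrix(ids=labels, values=d, shared=np.full((7, 7), 100))
        ours = bipartition_set(build_nj_tree(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        sk_dendro = tree_from_newick(str(sk_tree).strip(), rooted=False)
        assert ours == bipartition_set(sk_dendro)

    def test_undefined_distances_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        dm = DistanceMatrix(ids=["a", "b"], values=d, shared=np.zeros((2, 2)))
        with pytest.raises(DistanceError):
            build_nj_tree(dm)

    def test_negative_branch_clamped_with_warning(self):
        d = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], dtype=float
        )
        d[0, 1] = d[1, 0] = 0.0  # degenerate pair forces a negative length
        d[0, 2] = d[2, 0] = 2.0
        dm = DistanceMatrix(
            ids=list("abcd"), values=d, shared=np.full((4, 4), 10)
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = build_nj_tree(dm)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestMedianGenotype:
    def test_single_cell_group_is_that_row(self):
        m = matrix_from_rows({"a": [13, 14], "b": [15, 16]})
        med = median_genotype(m, ["a"])
        assert list(med) == [13, 14]

    def test_odd_group_median(self):
        m = matrix_from_rows({"a": [12], "b": [13], "c": [20]})
        assert median_genotype(m, ["a", "b", "c"])[0] == 13

    def test_even_group_lower_median(self):
        m = matrix_from_rows({"a": [12], "b": [14]})
        assert median_genotype(m, ["a", "b"])[0] == 12

    def test_missing_values_skipped(self):
        m = matrix_from_rows({"a": [np.nan], "b": [14], "c": [16]})
        assert median_genotype(m, ["a", "b", "c"])[0] == 14
        assert np.isnan(median_genotype(m, ["a"])[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_genotype(matrix_from_rows({"a": [1]}), [])


def clean_cluster_matrix():
    """Two tight clusters of cells plus a clear outgroup signature."""
    cols = 60
    base = np.full(cols, 13.0)
    rows = {}
    for i in range(3):
        row = base.copy()
        row[i] = 14
        row[40:50] = 15  # clade-1 shared mutations
        rows[f"x{i}"] = row
    for i in range(3):
        row = base.copy()
        row[10 + i] = 14
        row[50:60] = 16  # clade-2 shared mutations
        rows[f"y{i}"] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)


class TestRooting:
    def test_rooting_is_idempotent(self):
        m = clean_cluster_matrix()
        dm = mutation_count_distance(m, min_shared=1)
        tree = build_nj_tree(dm)
        founder = pd.Series(np.full(m.shape[1], 13.0), index=m.columns)
        r1 = root_tree(tree, m, genotype=founder, dm=dm, min_shared=1)
        r2 = root_tree(r1, m, genotype=founder, dm=dm, min_shared=1)
        assert r1.as_string(schema="newick") == r2.as_string(schema="newick")

    def test_root_separates_the_two_clades(self):
        m = clean_cluster_matrix()
        dm = mutation_count_distance(m, min_shared=1)
        tree = build_nj_tree(dm)
        founder = pd.Series(np.full(m.shape[1], 13.0), index=m.columns)
        rooted = root_tree(tree, m, genotype=founder, dm=dm, min_shared=1)
        children = rooted.seed_node.child_nodes()
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in children
        ]
        assert {"x0", "x1", "x2"} in sides or {"y0", "y1", "y2"} in sides

    def test_outgroup_and_nearest_edge_modes_agree(self):
        m = clean_cluster_matrix()
        dm = mutation_count_distance(m, min_shared=1)
        tree = build_nj_tree(dm)
        founder = pd.Series(np.full(m.shape[1], 13.0), index=m.columns)
        near = root_tree(tree, m, genotype=founder, dm=dm, min_shared=1)
        out = root_tree(
            tree, m, genotype=founder, mode="outgroup", dm=dm, min_shared=1
        )
        def clades(t):
            return {
                frozenset(l.taxon.label for l in n.leaf_iter())
                for n in t.preorder_internal_node_iter()
            }
        assert clades(near) == clades(out)

    def test_median_of_group_used_when_no_genotype_given(self):
        m = clean_cluster_matrix()
        dm = mutation_count_distance(m, min_shared=1)
        tree = build_nj_tree(dm)
        rooted = root_tree(tree, m, group=["x0", "x1", "x2"], dm=dm, min_shared=1)
        assert rooted.is_rooted

    def test_unknown_mode_rejected(self):
        m = clean_cluster_matrix()
        tree = build_nj_tree(mutation_count_distance(m, min_shared=1))
        with pytest.raises(ValueError, match="mode"):
            root_tree(tree, m, group=["x0"], mode="nope", min_shared=1)
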