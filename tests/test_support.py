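"""Bootstrap replicates, transfer distance/TBE, hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import (
    oracle_hypergeom_upper_tail,
    oracle_tbe,
    oracle_transfer_distance,
    random_binary_newick,
    tree_from_newick,
)
from strlineage.phylo import bipartition_set, build_nj_tree, leaf_labels, mutation_count_distance
from strlineage.support import (
    bootstrap_replicates,
    compute_tbe,
    hypergeometric_enrichment,
    tbe_for_split,
    transfer_distance,
)


def strong_signal_matrix(n_per_clade=4, n_loci=90):
    """Two clades with many private mutations each."""
    rows = {}
    base = np.full(n_loci, 13.0)
    for i in range(n_per_clade):
        row = base.copy()
        row[: n_loci // 3] = 15
        row[i] += 1
        rows[f"a{i}"] = row
    for i in range(n_per_clade):
        row = base.copy()
        row[n_loci // 3 : 2 * n_loci // 3] = 16
        row[40 + i] += 1
        rows[f"b{i}"] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)


class TestBootstrap:
    def test_keep_fraction_one_reproduces_full_tree(self):
        m = strong_signal_matrix()
        full = build_nj_tree(mutation_count_distance(m, min_shared=1))
        reps = bootstrap_replicates(
            m, keep_fraction=1.0, n_replicates=5, seed=0, min_shared=1
        )
        for t in reps:
            assert bipartition_set(t) == bipartition_set(full)

    def test_seed_reproducibility(self):
        m = strong_signal_matrix()
        a = bootstrap_replicates(m, n_replicates=10, seed=3, min_shared=1)
        b = bootstrap_replicates(m, n_replicates=10, seed=3, min_shared=1)
        assert [bipartition_set(t) for t in a] == [bipartition_set(t) for t in b]

    def test_replicates_preserve_leaf_set(self):
        m = strong_signal_matrix()
        reps = bootstrap_replicates(m, n_replicates=4, seed=1, min_shared=1)
        assert len(reps) == 4
        for t in reps:
            assert sorted(leaf_labels(t)) == sorted(m.index)

    def test_invalid_parameters(self):
        m = strong_signal_matrix()
        with pytest.raises(ValueError):
            bootstrap_replicates(m, n_replicates=0)
        with pytest.raises(ValueError):
            bootstrap_replicates(m, keep_fraction=0.0)


class TestTransferDistance:
    def test_present_bipartition_distance_zero(self):
        t = tree_from_newick("((a,b),(c,(d,e)));", rooted=False)
        assert transfer_distance(frozenset({"d", "e"}), t) == 0
        assert transfer_distance(frozenset({"a", "b"}), t) == 0

    def test_swapped_cherry_distance_one(self):
        t = tree_from_newick("((a,c),(b,(d,e)));", rooted=False)
        assert transfer_distance(frozenset({"a", "b"}), t) == 1

    def test_unknown_leaves_rejected(self):
        t = tree_from_newick("((a,b),c);", rooted=False)
        with pytest.raises(ValueError):
            transfer_distance(frozenset({"a", "z"}), t)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(8)]
        tree = tree_from_newick(random_binary_newick(labels, rng), rooted=False)
        # every bipartition side of size 2..6 drawn at random
        for _ in range(25):
            k = int(rng.integers(2, 7))
            side = frozenset(rng.choice(labels, size=k, replace=False))
            assert transfer_distance(side, tree) == oracle_transfer_distance(
                side, tree
            )


class TestTBE:
    def test_identical_replicates_give_full_support(self, rng):
        labels = [f"t{i}" for i in range(8)]
        nwk = random_binary_newick(labels, rng)
        ref = tree_from_newick(nwk, rooted=False)
        reps = [tree_from_newick(nwk, rooted=False) for _ in range(10)]
        for s in compute_tbe(ref, reps):
            assert s.tbe == pytest.approx(1.0)

    def test_p2_branch_always_absent_scores_zero(self):
        ref = tree_from_newick("((a,b),(c,d),e);", rooted=False)
        reps = [tree_from_newick("((a,c),(b,d),e);", rooted=False)] * 5
        supports = {frozenset(s.side): s for s in compute_tbe(ref, reps)}
        ab = supports[frozenset({"a", "b"})]
        assert ab.p == 2 and ab.tbe == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_six_leaf(self, seed):
        rng = np.random.default_rng(100 + seed)
        labels = [f"t{i}" for i in range(6)]
        ref = tree_from_newick(random_binary_newick(labels, rng), rooted=False)
        reps = [
            tree_from_newick(random_binary_newick(labels, rng), rooted=False)
            for _ in range(7)
        ]
        for s in compute_tbe(ref, reps):
            expected = oracle_tbe(s.side, reps, 6)
            assert s.tbe == pytest.approx(max(0.0, expected), abs=1e-12)

    def test_monotone_adding_ref_replicate(self, rng):
        labels = [f"t{i}" for i in range(7)]
        nwk = random_binary_newick(labels, rng)
        ref = tree_from_newick(nwk, rooted=False)
        reps = [
            tree_from_newick(random_binary_newick(labels, rng), rooted=False)
            for _ in range(5)
        ]
        before = {frozenset(s.side): s.tbe for s in compute_tbe(ref, reps)}
        reps_plus = reps + [tree_from_newick(nwk, rooted=False)]
        after = {frozenset(s.side): s.tbe for s in compute_tbe(ref, reps_plus)}
        for side, tbe in before.items():
            assert after[side] >= tbe - 1e-12

    def test_mismatched_leafsets_rejected(self):
        ref = tree_from_newick("((a,b),(c,d),e);", rooted=False)
        bad = tree_from_newick("((a,b),(c,d),f);", rooted=False)
        with pytest.raises(ValueError, match="leaf set"):
            compute_tbe(ref, [bad])

    def test_trivial_split_rejected(self):
        reps = [tree_from_newick("((a,b),(c,d),e);", rooted=False)]
        with pytest.raises(ValueError, match="p < 2"):
            tbe_for_split(frozenset({"a"}), reps, 5)


class TestEnrichment:
    def test_whole_tree_subtree_p_one(self):
        t = tree_from_newick("((a,b),(c,d));", rooted=True)
        labels = {"a": "x", "b": "x", "c": "y", "d": "y"}
        records = hypergeometric_enrichment(t, labels)
        root_records = [r for r in records if r.n == 4]
        assert root_records and all(r.p_value == pytest.approx(1.0) for r in root_records)

    def test_exact_enumerable_case_one_over_252(self):
        # N=10, K=5, n=5, k=5: a 5-leaf clade all carrying the 5-member label
        nwk = "(((((a1,a2),a3),a4),a5),((((b1,b2),b3),b4),b5));"
        t = tree_from_newick(nwk, rooted=True)
        labels = {f"a{i}": "A" for i in range(1, 6)}
        labels.update({f"b{i}": "B" for i in range(1, 6)})
        records = hypergeometric_enrichment(t, labels)
        hit = next(
            r for r in records if r.label == "A" and r.n == 5 and r.k == 5
        )
        assert hit.p_value == pytest.approx(1 / 252, abs=1e-12)
        assert hit.p_value == pytest.approx(
            oracle_hypergeom_upper_tail(5, 10, 5, 5), abs=1e-12
        )

    def test_survival_identity_vs_exact_tail(self):
        for N, K, n, k in [(12, 4, 6, 2), (20, 8, 5, 4), (9, 3, 3, 1)]:
            sf = float(stats.hypergeom.sf(k - 1, N, K, n))
            assert sf == pytest.approx(
                oracle_hypergeom_upper_tail(k, N, K, n), abs=1e-12
            )

    def test_invariance_under_label_renaming(self):
        t = tree_from_newick("(((a,b),c),((d,e),f));", rooted=True)
        labels = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "z", "f": "z"}
        renamed = {cell: lab.upper() for cell, lab in labels.items()}
        p1 = sorted(r.p_value for r in hypergeometric_enrichment(t, labels))
        p2 = sorted(r.p_value for r in hypergeometric_enrichment(t, renamed))
        assert p1 == pytest.approx(p2)

    def test_unlabeled_leaves_excluded_with_warning(self):
        t = tree_from_newick("((a,b),(c,d));", rooted=True)
        labels = {"a": "x", "b": "x", "c": "y"}
        with pytest.warns(UserWarning, match="unlabeled"):
            records = hypergeometric_enrichment(t, labels)
        assert all(r.N == 3 for r in records)

    def test_bh_adjustment_is_monotone_and_bounded(self):
        t = tree_from_newick("(((a,b),c),((d,e),f));", rooted=True)
        labels = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "y", "f": "x"}
        records = hypergeometric_enrichment(t, labels)
        for r in records:
            assert r.adjusted_p >= r.p_value - 1e-12
            assert r.adjusted_p <= 1.0

    def test_permutation_null_pvalues_super_uniform(self):
        # hypergeometric p-values are discrete, hence super-uniform under a
        # label permutation null: P(p <= t) <= t (up to Monte-Carlo error)
        rng = np.random.default_rng(0)
        labels_list = ["x"] * 4 + ["y"] * 4
        nwk = "(((a,b),(c,d)),((e,f),(g,h)));"
        t = tree_from_newick(nwk, rooted=True)
        cells = list("abcdefgh")
        pvals = []
        for _ in range(300):
            perm = rng.permutation(labels_list)
            labels = dict(zip(cells, perm))
            records = hypergeometric_enrichment(t, labels)
            pvals.extend(r.p_value for r in records if r.label == "x" and r.n < 8)
        pvals = np.array(pvals)
        for threshold in (0.01, 0.05, 0.1, 0.25, 0.5):
            emp = float((pvals <= threshold).mean())
            mc_slack = 3 * np.sqrt(threshold * (1 - threshold) / pvals.size) + 0.02
            assert emp <= threshold + mc_slack
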