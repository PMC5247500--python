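import dendropy
import numpy as np
import pytest
from scipy import stats

from morphobench.metrics import (depth_accuracy_correlation,
                                 majority_rule_consensus, per_node_accuracy,
                                 resolution, rf_distance)
from morphobench.trees import (Tree, make_asymmetric_tree, make_symmetric_tree,
                               random_resolved_tree)


def star(labels):
    n = len(labels)
    return Tree([[] for _ in range(n)] + [list(range(n))],
                [n] * n + [-1], [1.0] * n + [0.0], list(labels), n)


def dendropy_rf(a: Tree, b: Tree) -> int:
    tns = dendropy.TaxonNamespace(sorted(a.labels))
    da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                           taxon_namespace=tns)
    db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                           taxon_namespace=tns)
    da.encode_bipartitions()
    db.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(da, db)


class TestConsensus:
    def test_identical_inputs_return_topology(self):
        t = Tree.from_newick("((A,B),(C,D));")
        cons = majority_rule_consensus([t, t.copy(), t.copy()])
        assert cons.split_masks() == t.split_masks()

    def test_two_thirds_majority_retained(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        cons = majority_rule_consensus([t1, t1.copy(), t2])
        assert cons.split_masks() == t1.split_masks()

    def test_exact_half_dropped(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        cons = majority_rule_consensus([t1, t2])
        assert cons.split_masks() == set()  # strict majority rule

    def test_three_way_conflict_gives_star(self):
        trees = [Tree.from_newick(s) for s in
                 ("((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));")]
        assert majority_rule_consensus(trees).split_masks() == set()

    def test_mismatched_leaf_sets_rejected(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            majority_rule_consensus([t1, t2])

    def test_matches_dendropy_consensus(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        trees = [random_resolved_tree(labels, rng) for _ in range(7)]
        ours = majority_rule_consensus(trees)
        tns = dendropy.TaxonNamespace(sorted(labels))
        dtrees = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=tns) for t in trees]
        )
        dcons = dtrees.consensus(min_freq=0.5)
        theirs = Tree.from_dendropy(dcons)
        assert ours.split_masks() == theirs.split_masks()

    def test_output_is_valid_tree(self):
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(10)]
        trees = [random_resolved_tree(labels, rng) for _ in range(5)]
        cons = majority_rule_consensus(trees)
        assert sorted(cons.leaf_set(cons.root)) == sorted(labels)
        # every retained split must be compatible with all others
        masks = sorted(cons.split_masks())
        for i, a in enumerate(masks):
            for b in masks[i + 1:]:
                assert a & b in (0, a, b)


class TestRFDistance:
    def test_identical_zero(self):
        t = make_symmetric_tree(16)
        assert rf_distance(t, t.copy()) == 0

    def test_disjoint_quartets(self):
        a = Tree.from_newick("((A,B),(C,D));")
        b = Tree.from_newick("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_maximum_on_32_taxa_is_58(self):
        labels = [f"t{i + 1}" for i in range(32)]
        a = make_asymmetric_tree(32)
        interleaved = [x for pair in zip(labels[:16], labels[16:])
                       for x in pair]
        b = make_asymmetric_tree(32, labels=interleaved)
        assert rf_distance(a, b) == 58 == 2 * (32 - 3)

    def test_star_vs_resolved(self):
        t = make_symmetric_tree(16)
        assert rf_distance(t, star(t.labels)) == 16 - 3

    def test_matches_dendropy(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(9)]
        for _ in range(10):
            a = random_resolved_tree(labels, rng)
            b = random_resolved_tree(labels, rng)
            assert rf_distance(a, b) == dendropy_rf(a, b)

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(10):
            a, b, c = (random_resolved_tree(labels, rng) for _ in range(3))
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, a) == 0
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_mismatched_leaves_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(Tree.from_newick("((A,B),(C,D));"),
                        Tree.from_newick("((A,B),(C,E));"))


class TestResolution:
    def test_fully_resolved(self):
        assert resolution(make_symmetric_tree(32)) == 1.0

    def test_star_is_zero(self):
        assert resolution(star(list("ABCDE"))) == 0.0

    def test_partial(self):
        trees = [make_symmetric_tree(32),
                 make_asymmetric_tree(32)]
        cons = majority_rule_consensus(trees)
        k = len(cons.split_masks())
        assert resolution(cons, 32) == k / 29

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            resolution(star(list("ABC")))


class TestPerNodeAccuracy:
    def test_perfect_recovery(self):
        gt = make_symmetric_tree(8)
        table = per_node_accuracy(gt, [gt.copy() for _ in range(4)])
        assert (table["accuracy_pct"] == 100.0).all()
        assert table["depth"].min() >= 1

    def test_star_consensuses_score_zero(self):
        gt = make_symmetric_tree(8)
        table = per_node_accuracy(gt, [star(gt.labels)] * 3)
        assert (table["accuracy_pct"] == 0.0).all()

    def test_hand_counted_frequencies(self):
        gt = Tree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        c1 = gt.copy()
        c2 = Tree.from_newick("(((A,C),(B,D)),((E,F),(G,H)));")
        c3 = Tree.from_newick("(((A,B),(C,D)),((E,G),(F,H)));")
        c4 = star(gt.labels)
        table = per_node_accuracy(gt, [c1, c2, c3, c4]).set_index("clade")
        assert table.loc["A,B", "accuracy_pct"] == 50.0   # c1, c3
        assert table.loc["C,D", "accuracy_pct"] == 50.0
        assert table.loc["E,F", "accuracy_pct"] == 50.0   # c1, c2
        assert table.loc["A,B,C,D", "accuracy_pct"] == 75.0  # c1, c2, c3


class TestDepthAccuracyCorrelation:
    @staticmethod
    def _table(depths, accs):
        import pandas as pd
        return pd.DataFrame({"depth": depths, "accuracy_pct": accs})

    def test_monotone_extremes(self):
        t = self._table([1, 2, 3, 4], [10, 20, 30, 40])
        assert depth_accuracy_correlation(t).rho == pytest.approx(1.0)
        t = self._table([1, 2, 3, 4], [40, 30, 20, 10])
        assert depth_accuracy_correlation(t).rho == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        rng = np.random.default_rng(4)
        depths = rng.integers(1, 5, 10)
        accs = rng.integers(0, 4, 10) * 25.0
        if np.ptp(accs) == 0:
            accs[0] += 25.0
        t = self._table(depths, accs)
        got = depth_accuracy_correlation(t)
        # direct average-rank Pearson-of-ranks oracle
        r1 = stats.rankdata(depths)
        r2 = stats.rankdata(accs)
        expect = np.corrcoef(r1, r2)[0, 1]
        assert got.rho == pytest.approx(expect, abs=1e-12)

    def test_constant_accuracy_flagged(self):
        t = self._table([1, 2, 3], [50, 50, 50])
        res = depth_accuracy_correlation(t)
        assert not res.defined and np.isnan(res.rho)
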