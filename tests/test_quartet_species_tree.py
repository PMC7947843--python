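import itertools

import dendropy
import numpy as np
import pytest

from uceflow import msc_simulator as ms
from uceflow._treestate import TreeState
from uceflow.quartet_species_tree import (
    D_CAP, branch_support, coalescent_branch_length, quartet_score,
    quartet_table, root_with_outgroup, search_species_tree,
    summarize_gene_trees,
)
from .conftest import newick


def induced_quartet_oracle(tree, quartet):
    """Independent oracle: extract the 4-taxon induced tree with dendropy
    and read the cherry pairing off it."""
    sub = tree.extract_tree_with_taxa_labels(list(quartet))
    sub.encode_bipartitions()
    for bp in sub.bipartition_encoding:
        leaves = bp.leafset_taxa(sub.taxon_namespace)
        if len(leaves) == 2:
            return frozenset(t.label for t in leaves)
    return None  # unresolved


class TestQuartetTable:
    def test_identical_trees(self):
        ns = dendropy.TaxonNamespace(list("ABCD"))
        t = newick("((A,B),(C,D));", ns)
        tab = quartet_table([t] * 10, list("ABCD"))
        assert tab.counts.tolist() == [[10, 0, 0]]   # AB|CD is column 0

    def test_missing_taxon_contributes_nothing(self):
        ns = dendropy.TaxonNamespace(list("ABCDE"))
        full = newick("((A,B),(C,D),E);", ns)
        partial = newick("((A,B),C,E);", ns)      # no D
        tab = quartet_table([full, partial], list("ABCDE"))
        row_abcd = tab.row_of((0, 1, 2, 3))
        assert tab.counts[row_abcd].sum() == 1
        row_abce = tab.row_of((0, 1, 2, 4))
        assert tab.counts[row_abce].sum() == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_induced_quartet_oracle(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        trees = [TreeState.random_topology(8, rng).to_dendropy(taxa)
                 for _ in range(4)]
        tab = quartet_table(trees, taxa)
        pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        for qi, q in enumerate(map(tuple, tab.quartets)):
            names = [taxa[i] for i in q]
            expected = np.zeros(3)
            for tr in trees:
                cherry = induced_quartet_oracle(tr, names)
                for col, (p1, p2) in enumerate(pairs):
                    # a pairing is displayed iff either of its pairs is a
                    # cherry of the induced 4-taxon tree
                    if cherry in (frozenset((names[p1[0]], names[p1[1]])),
                                  frozenset((names[p2[0]], names[p2[1]]))):
                        expected[col] += 1
            assert np.array_equal(tab.counts[qi], expected), q


class TestQuartetScore:
    def test_complete_agreement_is_maximal(self):
        taxa = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(2)
        ts = TreeState.random_topology(6, rng)
        trees = [ts.to_dendropy(taxa) for _ in range(9)]
        tab = quartet_table(trees, taxa)
        assert quartet_score(ts, tab) == 15 * 9   # C(6,4) * G

    def test_true_tree_beats_nni_neighbors_on_consistent_data(self):
        taxa = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        ts = TreeState.random_topology(6, rng)
        tab = quartet_table([ts.to_dendropy(taxa)] * 5, taxa)
        s_true = quartet_score(ts, tab)
        for (u, v) in ts.internal_edges():
            for (x, y) in ts.nni_moves(u, v):
                alt = ts.copy()
                alt.apply_nni(u, v, x, y)
                assert quartet_score(alt, tab) < s_true

    def test_invariant_to_rerooting(self):
        taxa = list("ABCDEF")
        ns = dendropy.TaxonNamespace(taxa)
        gene = newick("(((A,B),(C,D)),(E,F));", ns)
        tab = quartet_table([gene] * 3, taxa)
        t1 = newick("(((A,B),(C,D)),(E,F));", ns)
        t2 = newick("(A,(B,((C,D),(E,F))));", ns)   # same unrooted shape
        assert quartet_score(t1, tab) == quartet_score(t2, tab)


class TestSearch:
    def test_consistent_gene_trees_recovered_exactly(self):
        taxa = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(7)
        truth = TreeState.random_topology(6, rng)
        tab = quartet_table([truth.to_dendropy(taxa)] * 12, taxa)
        res = search_species_tree(tab, seed=0)
        assert res.topology.splits() == truth.splits()
        assert res.score == quartet_score(truth, tab)

    @pytest.mark.parametrize("seed", range(10))
    def test_hill_climb_matches_exhaustive_n7(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(7)]
        trees = [TreeState.random_topology(7, rng).to_dendropy(taxa)
                 for _ in range(15)]
        tab = quartet_table(trees, taxa)
        exact = search_species_tree(tab, seed=seed)          # exhaustive
        climbed = search_species_tree(tab, seed=seed, exhaustive_max=4,
                                      n_restarts=5)
        assert climbed.score == exact.score

    def test_too_few_taxa_rejected(self):
        taxa = list("ABC")
        with pytest.raises(ValueError):
            ns = dendropy.TaxonNamespace(taxa)
            tab = quartet_table([newick("(A,B,C);", ns)], taxa)
            search_species_tree(tab)


class TestBranchSupport:
    def test_coalescent_length_formula(self):
        assert coalescent_branch_length(1 / 3)[0] == pytest.approx(0.0)
        assert coalescent_branch_length(0.9)[0] == pytest.approx(
            -np.log(0.15), abs=1e-12)
        d, flag = coalescent_branch_length(1.0)
        assert d == D_CAP and not flag
        assert coalescent_branch_length(0.2) == (0.0, True)

    def test_concordant_limit(self):
        taxa = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(1)
        ts = TreeState.random_topology(6, rng)
        tab = quartet_table([ts.to_dendropy(taxa)] * 20, taxa)
        for b in branch_support(ts, tab, taxa):
            assert b.q1 == pytest.approx(1.0)
            assert b.support == pytest.approx(1.0)
            assert b.coalescent_length == D_CAP

    def test_q_normalization(self):
        model, _ = _scenario()
        gts = ms.simulate_gene_trees(model, 150, seed=5)
        res = summarize_gene_trees(gts, model.taxa, seed=0)
        for b in res.branches:
            assert b.q1 + b.q2 + b.q3 == pytest.approx(1.0, abs=1e-9)

    def test_localpp_between_zero_and_one_and_tracks_q1(self):
        model, _ = _scenario()
        gts = ms.simulate_gene_trees(model, 150, seed=5)
        tab = quartet_table(gts, model.taxa)
        res = search_species_tree(tab, seed=0)
        freq = branch_support(res.topology, tab, model.taxa, method="freq")
        lpp = branch_support(res.topology, tab, model.taxa,
                             method="localpp")
        for f, l in zip(freq, lpp):
            assert 0.0 <= l.support <= 1.0
            if f.q1 > 0.6 and f.m > 50:
                assert l.support > 0.9


def _scenario():
    from uceflow.pipeline import three_clade_scenario

    return three_clade_scenario(taxa_per_clade=2, n_outgroup=2,
                                focal_length=1.0, clade_height=0.3)


class TestRooting:
    def test_single_outgroup_roots_on_pendant(self):
        tree = newick("((A,B),(C,D),E);")
        rooted = root_with_outgroup(tree, ["E"])
        kids = rooted.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"E"} in sides

    def test_outgroup_complement_symmetry(self):
        tree = newick("((A,B),(C,D),E);")
        r1 = root_with_outgroup(tree, ["A", "B"])
        r2 = root_with_outgroup(tree, ["C", "D", "E"])
        s1 = {frozenset(lf.taxon.label for lf in k.leaf_iter())
              for k in r1.seed_node.child_nodes()}
        s2 = {frozenset(lf.taxon.label for lf in k.leaf_iter())
              for k in r2.seed_node.child_nodes()}
        assert s1 == s2

    def test_scattered_outgroup_rejected(self):
        tree = newick("((A,B),(C,D),E);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(tree, ["A", "C"])


class TestMSCExpectations:
    @pytest.mark.parametrize("t_internal", [0.5, 2.0])
    def test_focal_d_recovery(self, t_internal):
        nwk = (f"(((A:1,B:1):{t_internal},C:{1 + t_internal}):4,"
               f"D:{5 + t_internal});")
        model = ms.SpeciesTreeModel.from_newick(nwk)
        gts = ms.simulate_gene_trees(model, 2000, seed=3)
        tab = quartet_table(gts, model.taxa)
        ts = TreeState.from_dendropy(
            newick("((A,B),(C,D));"),
            {t: i for i, t in enumerate(model.taxa)})
        branches = branch_support(ts, tab, model.taxa)
        assert len(branches) == 1
        assert branches[0].coalescent_length == pytest.approx(
            t_internal, abs=0.15)
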