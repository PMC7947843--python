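import itertools
import math

import dendropy
import numpy as np
import pytest
import scipy.linalg

from uceflow import msc_simulator as ms
from uceflow._treestate import TreeState
from uceflow.genetree_engine import (
    ConstraintHypothesis, LikelihoodEngine, SubstitutionModel,
    TaxonMismatchError, bic, bootstrap_supports, compress_patterns,
    log_likelihood, nni_search, optimize_branch_lengths,
    partitioned_likelihood, per_site_log_likelihoods, select_model,
    _tree_to_state,
)
from .conftest import make_locus, newick


def brute_force_loglik(nwk_template, lengths, model, locus):
    """Enumeration oracle for the 5-taxon tree ((A,B),(C,D),E).

    Sums over all internal-state assignments with transition matrices
    from scipy's expm — independent of the engine's eigen kernel.
    """
    Q = model.q_matrix()
    P = {k: scipy.linalg.expm(Q * t) for k, t in lengths.items()}
    b2i = {b: i for i, b in enumerate("ACGT")}
    pi = model.base_freqs
    total = 0.0
    M = locus.matrix
    for s in range(locus.n_sites):
        a, b, c, d, e = (b2i[M[i, s]] for i in range(5))
        lik = 0.0
        for z in range(4):
            for x in range(4):
                for y in range(4):
                    lik += (pi[z] * P["x"][z, x] * P["A"][x, a]
                            * P["B"][x, b] * P["y"][z, y] * P["C"][y, c]
                            * P["D"][y, d] * P["E"][z, e])
        total += math.log(lik)
    return total


class TestPatterns:
    def test_identical_columns_compress_to_one(self):
        locus = make_locus(["A" * 30, "C" * 30, "G" * 30])
        patterns, weights, inverse = compress_patterns(locus)
        assert patterns.shape == (3, 1)
        assert weights.tolist() == [30.0]

    def test_distinct_columns_stay_distinct(self):
        locus = make_locus(["ACGT", "CGTA", "GTAC"])
        patterns, weights, inverse = compress_patterns(locus)
        assert patterns.shape[1] == 4
        assert np.all(weights == 1)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        locus = make_locus(["".join(rng.choice(list("ACGT-"), 40))
                            for _ in range(5)])
        patterns, weights, inverse = compress_patterns(locus)
        assert weights.sum() == locus.n_sites
        assert np.array_equal(patterns[:, inverse], locus.matrix)


class TestLogLikelihood:
    def test_two_taxon_jc_closed_form(self):
        model = SubstitutionModel.jc69()
        locus = make_locus(["A", "A"], taxa=("A", "B"))
        tree = newick("(A:0.1,B:0.2);")
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * 0.3 / 3)))
        assert log_likelihood(tree, model, locus) == pytest.approx(expected,
                                                                   abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        taxa = tuple("ABCDE")
        locus = make_locus(["".join(rng.choice(list("ACGT"), 15))
                            for _ in range(5)], taxa=taxa)
        lengths = {k: float(rng.uniform(0.02, 0.6))
                   for k in ("A", "B", "C", "D", "E", "x", "y")}
        nwk = (f"((A:{lengths['A']},B:{lengths['B']}):{lengths['x']},"
               f"(C:{lengths['C']},D:{lengths['D']}):{lengths['y']},"
               f"E:{lengths['E']});")
        model = SubstitutionModel.hky85(2.3, np.array([0.3, 0.2, 0.2, 0.3]))
        got = log_likelihood(newick(nwk), model, locus)
        want = brute_force_loglik(nwk, lengths, model, locus)
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_lengths_identical_sequences(self):
        model = SubstitutionModel.jc69()
        L = 23
        locus = make_locus(["A" * L] * 4, taxa=tuple("ABCD"))
        tree = newick("((A:0,B:0):0,C:0,D:0);")
        assert log_likelihood(tree, model, locus) == \
            pytest.approx(L * math.log(0.25), abs=1e-9)

    def test_taxon_reorder_invariance(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        tree = nni_search(aln, hky_model, seed=0)
        base = log_likelihood(tree, hky_model, aln)
        rng = np.random.default_rng(1)
        perm = rng.permutation(aln.n_taxa)
        shuffled = aln.subset_taxa([aln.taxa[i] for i in perm])
        assert log_likelihood(tree, hky_model, shuffled) == \
            pytest.approx(base, abs=1e-8)

    def test_taxon_mismatch_rejected(self, hky_model):
        locus = make_locus(["ACGT"] * 4, taxa=tuple("ABCD"))
        with pytest.raises(TaxonMismatchError):
            log_likelihood(newick("((A,B),(C,E));"), hky_model, locus)

    def test_gamma_averages_category_likelihoods(self):
        model = SubstitutionModel.hky85(2.0, np.full(4, 0.25),
                                        gamma_alpha=0.7)
        locus = make_locus(["ACGTAC", "ACGAAG"], taxa=("A", "B"))
        tree = newick("(A:0.1,B:0.15);")
        got = log_likelihood(tree, model, locus)
        # oracle: per site, average plain-model likelihoods over the four
        # discrete-gamma category rates (rates scale the branch lengths)
        rates = model.category_rates()
        sitewise = []
        for j in range(locus.n_sites):
            col = locus.slice_sites(j, j + 1)
            liks = []
            for r in rates:
                plain = SubstitutionModel.hky85(2.0, np.full(4, 0.25))
                t = newick(f"(A:{0.1 * r:.17g},B:{0.15 * r:.17g});")
                liks.append(math.exp(log_likelihood(t, plain, col)))
            sitewise.append(math.log(np.mean(liks)))
        assert got == pytest.approx(sum(sitewise), abs=1e-9)


class TestBranchOptimization:
    def test_two_taxon_jc_mle_closed_form(self):
        rng = np.random.default_rng(5)
        S = 2000
        a = rng.choice(list("ACGT"), size=S)
        b = a.copy()
        flip = rng.random(S) < 0.2
        for i in np.flatnonzero(flip):
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        locus = make_locus(["".join(a), "".join(b)], taxa=("A", "B"))
        p_hat = (a != b).mean()
        out = optimize_branch_lengths(newick("(A:0.05,B:0.05);"),
                                      SubstitutionModel.jc69(), locus)
        total = sum(e.length for e in out.preorder_edge_iter() if e.length)
        mle = -0.75 * math.log(1 - 4 * p_hat / 3)
        assert total == pytest.approx(mle, abs=1e-4)

    def test_fixed_point_at_optimum(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        tree = nni_search(aln, hky_model, seed=0)
        again = optimize_branch_lengths(tree, hky_model, aln)
        assert again.log_likelihood == pytest.approx(tree.log_likelihood,
                                                     abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_ascent_property(self, seed, hky_model):
        rng = np.random.default_rng(seed)
        taxa = tuple("ABCDEF")
        locus = make_locus(["".join(rng.choice(list("ACGT"), 60))
                            for _ in range(6)], taxa=taxa)
        ts = TreeState.random_topology(6, rng, branch_length=0.2)
        tree = ts.to_dendropy(list(taxa))
        before = log_likelihood(tree, hky_model, locus)
        after = optimize_branch_lengths(tree, hky_model, locus)
        assert after.log_likelihood >= before - 1e-9


class TestNNISearch:
    def test_recovers_true_topology_with_strong_signal(self,
                                                       balanced6_model):
        hits = 0
        prof = ms.LocusProfile(length=1000, core_rate=0.3, flank_rate=1.0,
                               flank_rate_min=0.9, missing_prob=0.0,
                               subst_scale=0.08, flank_model=None)
        truth = {frozenset({"A", "B"}), frozenset({"C", "D"}),
                 frozenset({"E", "F"})}
        n_rep = 10
        for rep in range(n_rep):
            gt = ms.simulate_gene_trees(balanced6_model, 1, seed=100 + rep)[0]
            aln, _ = ms.simulate_locus_alignment(gt, prof, seed=rep)
            est = nni_search(aln, prof.model, seed=rep)
            splits = set()
            for nd in est.preorder_internal_node_iter():
                if nd.parent_node is None:
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if len(side) > 3:
                    side = frozenset(aln.taxa) - side
                splits.add(side)
            if truth <= {s for s in splits if len(s) == 2}:
                hits += 1
        assert hits >= n_rep - 1

    def test_constraint_always_displayed(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        con = ConstraintHypothesis.from_newick("X", "((A,E),B,C,D,F);")
        tree = nni_search(aln, hky_model, constraint=con, seed=0)
        sides = set()
        for nd in tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            sides.add(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
        assert frozenset({"A", "E"}) in {s if len(s) == 2 else
                                         frozenset(aln.taxa) - s
                                         for s in sides}

    def test_unconstrained_lnl_at_least_constrained(self, strong_locus,
                                                    hky_model):
        aln, _, _ = strong_locus
        con = ConstraintHypothesis.from_newick("X", "((A,E),B,C,D,F);")
        free = nni_search(aln, hky_model, seed=0)
        constrained = nni_search(aln, hky_model, constraint=con, seed=0)
        assert free.log_likelihood >= constrained.log_likelihood - 1e-6

    def test_incompatible_constraint_taxa_rejected(self, hky_model):
        locus = make_locus(["ACGTACGT"] * 4, taxa=tuple("ABCD"))
        con = ConstraintHypothesis.from_newick("X", "((Q,R),(S,T));")
        # constraint prunes to nothing -> uninformative, search is free
        tree = nni_search(locus, hky_model, constraint=con, seed=0)
        assert tree is not None


class TestModelSelection:
    def test_bic_formula(self):
        assert bic(-1234.5, 10, 600) == pytest.approx(
            2469.0 + 10 * math.log(600))

    def test_jc_data_prefers_jc(self, balanced6_model):
        prof = ms.LocusProfile(length=500, core_rate=0.3, flank_rate=1.0,
                               flank_rate_min=0.9, missing_prob=0.0,
                               subst_scale=0.08,
                               model=SubstitutionModel.jc69(),
                               flank_model=None)
        hits = 0
        for rep in range(5):
            gt = ms.simulate_gene_trees(balanced6_model, 1, seed=40 + rep)[0]
            aln, _ = ms.simulate_locus_alignment(gt, prof, seed=rep)
            chosen = select_model(aln, with_gamma=False)
            hits += chosen.name == "JC69"
        assert hits >= 4

    def test_strong_rate_variation_prefers_gamma(self, balanced6_model):
        prof = ms.LocusProfile(length=600, core_rate=0.02, flank_rate=3.0,
                               flank_rate_min=0.1, missing_prob=0.0,
                               subst_scale=0.15, flank_model=None)
        hits = 0
        for rep in range(3):
            gt = ms.simulate_gene_trees(balanced6_model, 1, seed=60 + rep)[0]
            aln, _ = ms.simulate_locus_alignment(gt, prof, seed=rep)
            chosen = select_model(aln, candidates=("HKY85",))
            hits += chosen.gamma_alpha is not None
        assert hits >= 2


class TestBootstrap:
    def test_single_clean_pattern_gives_full_support(self):
        locus = make_locus(["AAAA", "AAAA", "TTTT", "TTTT"],
                           taxa=tuple("ABCD"))
        model = SubstitutionModel.jc69()
        ml = nni_search(locus, model, seed=0)
        bs = bootstrap_supports(locus, model, ml, replicates=25, seed=1)
        labels = [nd.label for nd in bs.preorder_internal_node_iter()
                  if nd.label]
        assert labels and all(float(l) == 100.0 for l in labels)

    def test_one_replicate_is_zero_or_hundred(self, strong_locus,
                                              hky_model):
        aln, _, _ = strong_locus
        ml = nni_search(aln, hky_model, seed=0)
        bs = bootstrap_supports(aln, hky_model, ml, replicates=1, seed=2)
        for nd in bs.preorder_internal_node_iter():
            if nd.label:
                assert float(nd.label) in (0.0, 100.0)

    def test_deterministic_per_seed(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        ml = nni_search(aln, hky_model, seed=0)
        a = bootstrap_supports(aln, hky_model, ml, 40, seed=7)
        b = bootstrap_supports(aln, hky_model, ml, 40, seed=7)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")


class TestPartitioned:
    def test_identical_models_unit_multipliers_match_unpartitioned(
            self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        tree = nni_search(aln, hky_model, seed=0)
        segs = [(aln.slice_sites(0, 300, "a"), hky_model),
                (aln.slice_sites(300, 600, "b"), hky_model)]
        joint = partitioned_likelihood(segs, tree)
        assert joint == pytest.approx(tree.log_likelihood, abs=1e-6)

    def test_optimized_partitioned_nests_unpartitioned(self, strong_locus,
                                                       hky_model):
        aln, _, _ = strong_locus
        tree = nni_search(aln, hky_model, seed=0)
        segs = [(aln.slice_sites(0, 200, "a"), hky_model),
                (aln.slice_sites(200, 400, "b"), hky_model),
                (aln.slice_sites(400, 600, "c"), hky_model)]
        lnl = partitioned_likelihood(segs, tree, optimize_rates=True,
                                     optimize_branches=True)
        assert lnl >= tree.log_likelihood - 1e-6

    def test_partitioned_bic_wins_on_heterogeneous_data(
            self, balanced6_model):
        prof = ms.LocusProfile(length=450, core_rate=0.05, flank_rate=1.5,
                               missing_prob=0.0, subst_scale=0.1)
        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            gt = ms.simulate_gene_trees(balanced6_model, 1,
                                        seed=700 + rep)[0]
            aln, bp = ms.simulate_locus_alignment(gt, prof, seed=rep)
            tree = nni_search(aln, prof.model, seed=rep)
            segs = [(aln.slice_sites(0, bp[0], "L"), prof.model),
                    (aln.slice_sites(*bp, "c"), prof.model),
                    (aln.slice_sites(bp[1], aln.n_sites, "R"), prof.model)]
            lnl_part = partitioned_likelihood(segs, tree,
                                              optimize_rates=True,
                                              optimize_branches=True)
            k_extra = 2  # independent rate multipliers beyond the mean
            if bic(lnl_part, k_extra, aln.n_sites) < bic(
                    tree.log_likelihood, 0, aln.n_sites):
                wins += 1
        assert wins >= 4

    def test_taxon_mismatch_rejected(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        other = aln.subset_taxa(list(aln.taxa[:4]))
        with pytest.raises(TaxonMismatchError):
            LikelihoodEngine.partitioned([(aln, hky_model),
                                          (other, hky_model)])


class TestSiteLikelihoods:
    def test_row_sums_equal_total_loglik(self, strong_locus, hky_model):
        aln, _, _ = strong_locus
        t1 = nni_search(aln, hky_model, seed=0)
        con = ConstraintHypothesis.from_newick("X", "((A,E),B,C,D,F);")
        t2 = nni_search(aln, hky_model, constraint=con, seed=0)
        mat = per_site_log_likelihoods([t1, t2], hky_model, aln)
        assert mat.matrix.shape == (2, aln.n_sites)
        assert mat.total_logliks()[0] == pytest.approx(t1.log_likelihood,
                                                       abs=1e-8)
        assert mat.total_logliks()[1] == pytest.approx(t2.log_likelihood,
                                                       abs=1e-8)

    def test_duplicated_tree_gives_identical_rows(self, strong_locus,
                                                  hky_model):
        aln, _, _ = strong_locus
        t1 = nni_search(aln, hky_model, seed=0)
        mat = per_site_log_likelihoods([t1, t1], hky_model, aln)
        assert np.allclose(mat.matrix[0], mat.matrix[1])

    @pytest.mark.parametrize("seed", range(3))
    def test_cells_match_single_site_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        taxa = tuple("ABCDE")
        locus = make_locus(["".join(rng.choice(list("ACGT"), 8))
                            for _ in range(5)], taxa=taxa)
        lengths = {k: float(rng.uniform(0.05, 0.4))
                   for k in ("A", "B", "C", "D", "E", "x", "y")}
        nwk = (f"((A:{lengths['A']},B:{lengths['B']}):{lengths['x']},"
               f"(C:{lengths['C']},D:{lengths['D']}):{lengths['y']},"
               f"E:{lengths['E']});")
        model = SubstitutionModel.hky85(1.7, np.array([0.3, 0.2, 0.2, 0.3]))
        mat = per_site_log_likelihoods([newick(nwk)], model, locus)
        for s in range(locus.n_sites):
            col = locus.slice_sites(s, s + 1)
            want = brute_force_loglik(nwk, lengths, model, col)
            assert mat.matrix[0, s] == pytest.approx(want, abs=1e-8)


class TestTreeState:
    def test_enumeration_counts(self):
        assert sum(1 for _ in TreeState.enumerate_topologies(5)) == 15
        assert sum(1 for _ in TreeState.enumerate_topologies(6)) == 105

    def test_enumerated_topologies_distinct(self):
        seen = set()
        for ts in TreeState.enumerate_topologies(6):
            seen.add(frozenset(ts.splits()))
        assert len(seen) == 105

    def test_nni_roundtrip_restores_splits(self):
        rng = np.random.default_rng(0)
        ts = TreeState.random_topology(8, rng)
        before = ts.splits()
        (u, v) = ts.internal_edges()[0]
        (x, y) = ts.nni_moves(u, v)[0]
        ts.apply_nni(u, v, x, y)
        moved = ts.splits()
        ts.apply_nni(u, v, y, x)
        assert moved != before
        assert ts.splits() == before

    def test_dendropy_roundtrip(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(7)]
        ts = TreeState.random_topology(7, rng)
        tree = ts.to_dendropy(labels)
        back = TreeState.from_dendropy(tree,
                                       {l: i for i, l in enumerate(labels)})
        assert back.splits() == ts.splits()
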