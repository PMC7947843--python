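import numpy as np
import pytest

from uceflow import msc_simulator as ms
from uceflow.msc_simulator import (
    InvalidModelError, LocusProfile, SpeciesTreeModel, SyntheticDataset,
    inject_missing_taxa, simulate_dataset, simulate_gene_trees,
    simulate_locus_alignment,
)
from uceflow.swsc_partitioner import entropy_profile


def sister_fraction(trees, pair):
    """Fraction of gene trees in which ``pair`` are sisters."""
    hits = 0
    for t in trees:
        for nd in t.preorder_internal_node_iter():
            labs = sorted(lf.taxon.label for lf in nd.leaf_iter())
            if labs == sorted(pair):
                hits += 1
                break
    return hits / len(trees)


class TestSpeciesTreeModel:
    def test_nonbinary_rejected(self):
        with pytest.raises(InvalidModelError):
            SpeciesTreeModel.from_newick("(A:1,B:1,C:1);")

    def test_negative_length_rejected(self):
        with pytest.raises(InvalidModelError):
            SpeciesTreeModel.from_newick("((A:1,B:-0.5):1,C:2);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(InvalidModelError):
            SpeciesTreeModel.from_newick("((A:1,A:1):1,C:2);")


class TestGeneTreeSimulation:
    def test_star_tree_yields_uniform_triplets(self):
        model = SpeciesTreeModel.from_newick("((A:1,B:1):0.0,C:1);")
        trees = simulate_gene_trees(model, 3000, seed=1)
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert sister_fraction(trees, pair) == pytest.approx(
                1 / 3, abs=0.03)

    def test_msc_triplet_probability_at_t1(self):
        model = SpeciesTreeModel.from_newick("((A:1,B:1):1.0,C:2);")
        trees = simulate_gene_trees(model, 5000, seed=7)
        expected = 1 - (2 / 3) * np.exp(-1.0)
        assert sister_fraction(trees, ("A", "B")) == pytest.approx(
            expected, abs=0.02)

    def test_no_ils_limit(self):
        model = SpeciesTreeModel.from_newick("((A:1,B:1):20.0,C:21);")
        trees = simulate_gene_trees(model, 300, seed=2)
        assert sister_fraction(trees, ("A", "B")) == 1.0

    def test_deterministic_and_counts(self):
        model = SpeciesTreeModel.from_newick("((A:1,B:1):1,C:2);")
        a = simulate_gene_trees(model, 20, seed=3)
        b = simulate_gene_trees(model, 20, seed=3)
        assert len(a) == 20
        assert [t.as_string(schema="newick") for t in a] == \
               [t.as_string(schema="newick") for t in b]

    def test_trees_span_all_taxa(self):
        model = ms.random_ultrametric_tree([f"s{i}" for i in range(9)],
                                           seed=4)
        for t in simulate_gene_trees(model, 5, seed=5):
            assert sorted(lf.taxon.label for lf in t.leaf_node_iter()) == \
                sorted(model.taxa)


class TestLocusProfile:
    def test_breakpoint_arithmetic(self):
        prof = LocusProfile(length=600, core_fraction=1 / 3,
                            missing_prob=0.0)
        assert prof.breakpoints() == (200, 400)

    def test_core_fraction_bounds(self):
        with pytest.raises(ValueError):
            LocusProfile(core_fraction=1.0)

    def test_core_slower_than_flank_floor(self):
        with pytest.raises(ValueError):
            LocusProfile(core_rate=0.7, flank_rate_min=0.5, flank_rate=1.0)

    def test_site_rates_shape(self):
        prof = LocusProfile(length=600, missing_prob=0.0)
        rates = prof.site_rates()
        l, r = prof.breakpoints()
        assert rates.shape == (600,)
        assert np.all(rates[l:r] == prof.core_rate)
        # flanks rise monotonically away from the core
        assert np.all(np.diff(rates[:l]) <= 0)
        assert np.all(np.diff(rates[r:]) >= 0)
        assert rates[:l].min() >= prof.flank_rate_min - 1e-12


class TestLocusAlignment:
    def test_zero_core_rate_gives_constant_core(self, balanced6_model):
        gt = simulate_gene_trees(balanced6_model, 1, seed=9)[0]
        prof = LocusProfile(length=300, core_rate=0.0, flank_rate=1.0,
                            flank_rate_min=0.5, missing_prob=0.0)
        aln, (l, r) = simulate_locus_alignment(gt, prof, seed=2)
        core = aln.matrix[:, l:r]
        assert all(len(set(core[:, j])) == 1 for j in range(r - l))

    def test_core_entropy_below_flank_entropy(self, balanced6_model):
        trees = simulate_gene_trees(balanced6_model, 20, seed=10)
        prof = LocusProfile(length=600, core_rate=0.05, flank_rate=1.0,
                            missing_prob=0.0)
        core_means, flank_means = [], []
        for i, gt in enumerate(trees):
            aln, (l, r) = simulate_locus_alignment(gt, prof, seed=50 + i)
            H = entropy_profile(aln)
            core_means.append(H[l:r].mean())
            flank_means.append(np.concatenate([H[:l], H[r:]]).mean())
        assert np.mean(core_means) < np.mean(flank_means)
        # strong separation, not a marginal pass
        assert np.mean(core_means) < 0.5 * np.mean(flank_means)

    def test_alignment_dimensions_and_determinism(self, balanced6_model):
        gt = simulate_gene_trees(balanced6_model, 1, seed=11)[0]
        prof = LocusProfile(length=240, missing_prob=0.0)
        a1, bp1 = simulate_locus_alignment(gt, prof, seed=3)
        a2, bp2 = simulate_locus_alignment(gt, prof, seed=3)
        assert a1.n_sites == 240 and bp1 == bp2
        assert np.array_equal(a1.matrix, a2.matrix)


class TestMissingTaxa:
    def _dataset(self, n_loci=100, n_taxa=20, seed=0):
        model = ms.random_ultrametric_tree([f"s{i:02d}" for i in
                                            range(n_taxa)], seed=seed)
        prof = LocusProfile(length=60, missing_prob=0.0)
        return simulate_dataset(model, prof, n_loci, seed=seed)

    def test_p_zero_is_identity(self):
        ds = self._dataset(10)
        out = inject_missing_taxa(ds, 0.0, seed=1)
        assert all(a.taxa == b.taxa for a, b in zip(out.loci, ds.loci))

    def test_retained_fraction_matches_binomial(self):
        ds = self._dataset(100, 20)
        out = inject_missing_taxa(ds, 0.2, min_taxa=4, seed=5)
        retained = sum(l.n_taxa for l in out.loci) / (100 * 20)
        assert retained == pytest.approx(0.8, abs=0.03)

    def test_min_taxa_floor(self):
        ds = self._dataset(30, 8)
        out = inject_missing_taxa(ds, 0.9, min_taxa=4, seed=6)
        assert min(l.n_taxa for l in out.loci) >= 4

    def test_p_one_rejected(self):
        ds = self._dataset(5)
        with pytest.raises(ValueError):
            inject_missing_taxa(ds, 1.0)

    def test_gene_tree_truth_untouched(self):
        ds = self._dataset(10)
        before = [t.as_string(schema="newick") for t in ds.gene_trees]
        out = inject_missing_taxa(ds, 0.5, seed=2)
        after = [t.as_string(schema="newick") for t in out.gene_trees]
        assert before == after


class TestDatasetIO:
    def test_write_dataset_layout(self, tmp_path):
        model = ms.random_ultrametric_tree(list("ABCDE"), seed=1)
        prof = LocusProfile(length=60, missing_prob=0.0)
        ds = simulate_dataset(model, prof, 3, seed=2)
        ms.write_dataset(ds, tmp_path)
        assert len(list((tmp_path / "loci").glob("*.fasta"))) == 3
        assert (tmp_path / "true_gene_trees.nwk").exists()
        truth = (tmp_path / "truth.tsv").read_text().splitlines()
        assert len(truth) == 4  # header + 3 loci
        assert (tmp_path / "manifest.json").exists()

    def test_invariant_one_tree_per_locus(self):
        model = ms.random_ultrametric_tree(list("ABCDE"), seed=1)
        prof = LocusProfile(length=60, missing_prob=0.0)
        ds = simulate_dataset(model, prof, 3, seed=2)
        with pytest.raises(ValueError):
            SyntheticDataset(ds.loci[:2], ds.gene_trees, ds.breakpoints,
                             ds.species_tree)
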