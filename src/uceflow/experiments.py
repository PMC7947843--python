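"""Synthetic validation experiments for the whole pipeline.

Each function runs one self-contained study on simulated data — the
analytic MSC check, likelihood-oracle comparisons, breakpoint recovery,
AU-test calibration, GGI directional power, the partitioning-benefit
comparison, and quartet species-tree checks — and returns plain numbers.
The acceptance script reports them; the test suite asserts them.  All
randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from . import msc_simulator as ms
from .genetree_engine import (SubstitutionModel, log_likelihood,
                              optimize_branch_lengths)
from .ggi_tester import GGIConfig, au_pvalue, ggi_corpus, ggi_tally, \
    rell_bootstrap
from .locus_profiler import holm_adjust, mean_support, paired_support_test
from .locus_store import LocusAlignment
from .pipeline import estimate_gene_trees, three_clade_scenario
from .quartet_species_tree import (branch_support, quartet_table,
                                   search_species_tree)
from .swsc_partitioner import best_breakpoints, entropy_profile
from ._treestate import TreeState

__all__ = [
    "msc_analytic_check", "likelihood_oracle", "breakpoint_recovery",
    "au_machinery", "ggi_directional_power", "partitioning_benefit",
    "quartet_checks", "bookkeeping_checks",
]


# ------------------------------------------------------ 1: MSC analytics

def msc_analytic_check(seed: int, n_genes: int = 5000) -> dict:
    """Triplet concordance under ((A,B):1, C) vs 1 - (2/3)e^-1."""
    model = ms.SpeciesTreeModel.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")
    trees = ms.simulate_gene_trees(model, n_genes, seed=seed)
    hits = 0
    for t in trees:
        for nd in t.preorder_internal_node_iter():
            labs = sorted(lf.taxon.label for lf in nd.leaf_iter())
            if labs == ["A", "B"]:
                hits += 1
                break
    frac = hits / n_genes
    expected = 1.0 - (2.0 / 3.0) * math.exp(-1.0)
    return {"concordant_fraction": frac, "expected": expected,
            "abs_error": abs(frac - expected), "n": n_genes}


# --------------------------------------------------- 2: likelihood oracle

def _enumeration_loglik(lengths, model, locus):
    """Brute-force 5-taxon likelihood by summing over internal states."""
    import scipy.linalg

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


def likelihood_oracle(seed: int, n_instances: int = 20) -> dict:
    """Pruning vs state-enumeration lnL, and the two-taxon JC MLE."""
    import dendropy

    rng = np.random.default_rng(seed)
    model = SubstitutionModel.hky85(2.3, np.array([0.3, 0.2, 0.2, 0.3]))
    max_err = 0.0
    for _ in range(n_instances):
        locus = LocusAlignment(
            "x", tuple("ABCDE"),
            rng.choice(list("ACGT"), size=(5, 12)))
        lengths = {k: float(rng.uniform(0.02, 0.6))
                   for k in ("A", "B", "C", "D", "E", "x", "y")}
        nwk = (f"((A:{lengths['A']},B:{lengths['B']}):{lengths['x']},"
               f"(C:{lengths['C']},D:{lengths['D']}):{lengths['y']},"
               f"E:{lengths['E']});")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        got = log_likelihood(tree, model, locus)
        want = _enumeration_loglik(lengths, model, locus)
        max_err = max(max_err, abs(got - want))
    # JC MLE closed form
    S = 1500
    a = rng.choice(list("ACGT"), size=S)
    b = a.copy()
    flip = rng.random(S) < 0.2
    for i in np.flatnonzero(flip):
        b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
    p_hat = float((a != b).mean())
    locus = LocusAlignment("jc", ("A", "B"), np.stack([a, b]))
    tree = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
    fitted = optimize_branch_lengths(tree, SubstitutionModel.jc69(), locus)
    total = sum(e.length for e in fitted.preorder_edge_iter() if e.length)
    mle = -0.75 * math.log(1.0 - 4.0 * p_hat / 3.0)
    return {"max_loglik_error": max_err,
            "jc_mle_error": abs(total - mle),
            "n": n_instances}


# ------------------------------------------------- 3: breakpoint recovery

def breakpoint_recovery(seed: int, n_loci: int = 50,
                        n_oracle_profiles: int = 5) -> dict:
    """Core-boundary recovery on 30-taxon 600-bp loci + SSE oracle."""
    taxa = [f"t{i:02d}" for i in range(30)]
    model = ms.random_ultrametric_tree(taxa, seed=seed, height=3.0)
    profile = ms.LocusProfile(length=600, core_rate=0.05, flank_rate=1.0,
                              missing_prob=0.0)
    trees = ms.simulate_gene_trees(model, n_loci, seed=seed)
    hits = 0
    for i, gt in enumerate(trees):
        aln, (l, r) = ms.simulate_locus_alignment(gt, profile,
                                                  seed=1000 * seed + i)
        s = best_breakpoints(entropy_profile(aln), 50)
        if abs(s.left - l) <= 25 and abs(s.right - r) <= 25:
            hits += 1
    # exact agreement with the cubic oracle on short random profiles
    rng = np.random.default_rng(seed + 1)
    agree = 0
    max_obj_err = 0.0
    for _ in range(n_oracle_profiles):
        L = int(rng.integers(80, 201))
        H = rng.random(L) * 2.0
        s = best_breakpoints(H, 20)
        o_sse, o_l, o_r = _cubic_oracle(H, 20)
        agree += (s.left, s.right) == (o_l, o_r)
        max_obj_err = max(max_obj_err, abs(s.objective - o_sse))
    return {"recovery_fraction": hits / n_loci,
            "oracle_breakpoint_agreement": agree / n_oracle_profiles,
            "oracle_max_objective_error": max_obj_err,
            "n": n_loci}


def _cubic_oracle(H, min_len):
    L = len(H)
    best = (np.inf, -1, -1)
    for l in range(min_len, L - 2 * min_len + 1):
        for r in range(l + min_len, L - min_len + 1):
            sse = 0.0
            for a, b in ((0, l), (l, r), (r, L)):
                seg = H[a:b]
                sse += float(np.sum((seg - seg.mean()) ** 2))
            if sse < best[0] - 1e-12:
                best = (sse, l, r)
    return best


# ------------------------------------------------------- 4: AU machinery

def au_machinery(seed: int) -> dict:
    """Dominance fixture, (c, d) inverse-model round trip, normalization."""
    rng = np.random.default_rng(seed)
    M = np.zeros((2, 120))
    M[0] += 0.5
    bp = rell_bootstrap(M, replicates=500, seed=seed)
    dominant_p = au_pvalue(bp[:, 0], replicates=500).p
    norm_err = float(np.abs(bp.sum(axis=1) - 1.0).max())
    scales = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4])
    max_cd = max_p = 0.0
    for _ in range(5):
        c = float(rng.uniform(-0.5, 0.5))
        d = float(rng.uniform(-0.5, 1.2))
        curve = 1.0 - norm.cdf(d * np.sqrt(scales) + c / np.sqrt(scales))
        fit = au_pvalue(curve, scales, replicates=10 ** 9)
        max_cd = max(max_cd, abs(fit.c - c), abs(fit.d - d))
        max_p = max(max_p, abs(fit.p - (1.0 - norm.cdf(d - c))))
    return {"dominant_p": dominant_p, "bp_normalization_error": norm_err,
            "cd_roundtrip_max_error": max_cd,
            "p_roundtrip_max_error": max_p, "n": 5}


# -------------------------------------------------- 5: GGI directional power

def ggi_directional_power(seed: int, n_loci: int = 200,
                          replicates: int = 500) -> dict:
    """H1-truth corpus: significant-locus counts per hypothesis, plus the
    indistinguishable-hypotheses control (duplicated site-lnL rows)."""
    model, hyps = three_clade_scenario(taxa_per_clade=3, n_outgroup=3,
                                       focal_length=1.0, clade_height=0.2)
    profile = ms.LocusProfile(length=300, missing_prob=0.0)
    ds = ms.simulate_dataset(model, profile, n_loci, seed=seed)
    config = GGIConfig(hypotheses=hyps, include_unconstrained=False,
                       replicates=replicates, seed=seed,
                       model=profile.model, max_moves=25)
    results, skipped = ggi_corpus(ds.loci, config)
    tally = ggi_tally(results)
    # control: two hypotheses with identical site-likelihood rows
    dup_sig = 0
    for r in results:
        k = r.tree_labels.index("H1")
        M = np.vstack([r.site_logliks.matrix[k], r.site_logliks.matrix[k]])
        bp = rell_bootstrap(M, replicates=replicates, seed=seed + 7)
        fits = [au_pvalue(bp[:, j], replicates=replicates)
                for j in range(2)]
        best = int(np.argmax(M.sum(axis=1)))
        if fits[best].p > 0.95:
            dup_sig += 1
    return {
        "h1_significant": tally.count("H1", significant=True),
        "h2_significant": tally.count("H2", significant=True),
        "h1_best": tally.count("H1"), "h2_best": tally.count("H2"),
        "indistinguishable_significant": dup_sig,
        "n_tested": len(results), "n_skipped": len(skipped),
        "n": n_loci,
    }


# ------------------------------------------------- 6: partitioning benefit

def partitioning_benefit(seed: int, n_loci: int = 100,
                         n_datasets: int = 3,
                         replicates: int = 100) -> dict:
    """Partitioned vs unpartitioned mean gene-tree bootstrap, with the
    paired one-sided Wilcoxon per dataset and Holm across datasets."""
    from .swsc_partitioner import partition_loci

    model, _ = three_clade_scenario(taxa_per_clade=3, n_outgroup=3,
                                    focal_length=1.0, clade_height=0.5,
                                    subst_scale=0.03)
    profile = ms.LocusProfile(length=300, core_rate=0.05, flank_rate=3.0,
                              flank_rate_min=0.6, subst_scale=0.03,
                              missing_prob=0.0)
    raws, diffs = [], []
    for d in range(n_datasets):
        ds = ms.simulate_dataset(model, profile, n_loci,
                                 seed=seed + 1000 * d)
        schemes = partition_loci(ds.loci, 50)
        unpart = estimate_gene_trees(ds.loci, profile.model,
                                     bootstrap_replicates=replicates,
                                     seed=seed)
        part = estimate_gene_trees(ds.loci, profile.model, schemes=schemes,
                                   bootstrap_replicates=replicates,
                                   seed=seed)
        before = {k: mean_support(t) for k, t in unpart.items()}
        after = {k: mean_support(t) for k, t in part.items()}
        before = {k: v for k, v in before.items() if v is not None}
        after = {k: v for k, v in after.items() if v is not None}
        raws.append(paired_support_test(before, after))
        diffs.append(float(np.mean([after[k] - before[k] for k in before])))
    adjusted = holm_adjust(raws)
    return {"p_raw": [float(p) for p in raws],
            "p_holm": [float(p) for p in adjusted],
            "min_p_holm": float(np.min(adjusted)),
            "mean_support_gain": [float(d) for d in diffs],
            "n": n_loci}


# ---------------------------------------------------- 7: quartet checks

def quartet_checks(seed: int, n_tree_sets: int = 20,
                   n_genes_d: int = 2000) -> dict:
    """Hill-climb vs exhaustive quartet optimum (n=7) and coalescent
    branch-length recovery for t in {0.5, 1, 2}."""
    rng = np.random.default_rng(seed)
    taxa7 = [f"t{i}" for i in range(7)]
    matches = 0
    for _ in range(n_tree_sets):
        trees = [TreeState.random_topology(7, rng).to_dendropy(taxa7)
                 for _ in range(15)]
        tab = quartet_table(trees, taxa7)
        exact = search_species_tree(tab, seed=seed)
        climbed = search_species_tree(tab, seed=seed, exhaustive_max=4,
                                      n_restarts=5)
        matches += climbed.score == exact.score
    d_errors = {}
    import dendropy

    for t in (0.5, 1.0, 2.0):
        nwk = f"(((A:1,B:1):{t},C:{1 + t}):4,D:{5 + t});"
        model = ms.SpeciesTreeModel.from_newick(nwk)
        gts = ms.simulate_gene_trees(model, n_genes_d, seed=seed + int(10 * t))
        tab = quartet_table(gts, model.taxa)
        ts = TreeState.from_dendropy(
            dendropy.Tree.get(data="((A,B),(C,D));", schema="newick"),
            {x: i for i, x in enumerate(model.taxa)})
        b = branch_support(ts, tab, model.taxa)[0]
        d_errors[t] = abs(b.coalescent_length - t)
    return {"hillclimb_matches_exhaustive": matches / n_tree_sets,
            "d_abs_error_t05": d_errors[0.5],
            "d_abs_error_t10": d_errors[1.0],
            "d_abs_error_t20": d_errors[2.0],
            "n": n_tree_sets}


# ------------------------------------------------------ 8: bookkeeping

def bookkeeping_checks(seed: int) -> dict:
    """Completeness filters, top-k selection and GGI tallies against
    hand-computed answers on synthetic manifests."""
    from .ggi_tester import AUFit, AUTestResult, UNCONSTRAINED, ggi_tally
    from .locus_profiler import LocusStats, rank_and_select
    from .locus_store import filter_by_completeness

    rng = np.random.default_rng(seed)
    total_taxa = 20
    counts = rng.integers(5, 21, size=100)
    loci = [LocusAlignment(f"l{i:03d}",
                           tuple(f"t{j}" for j in range(int(n))),
                           np.full((int(n), 8), "A", dtype="U1"))
            for i, n in enumerate(counts)]
    ok75 = [l.locus_id for l in
            filter_by_completeness(loci, total_taxa, 0.75)] == \
        [f"l{i:03d}" for i, n in enumerate(counts) if n >= 15]
    ok90 = [l.locus_id for l in
            filter_by_completeness(loci, total_taxa, 0.90)] == \
        [f"l{i:03d}" for i, n in enumerate(counts) if n >= 18]
    stats = [LocusStats(f"l{i}", gc=g)
             for i, g in enumerate([0.2, 0.4, 0.4, 0.1, 0.5])]
    topk = rank_and_select(stats, "gc", 3)
    ok_topk = topk == ["l3", "l0", "l1"] and len(topk) == 3

    def result(lid, best, p):
        labels = ["H1", "H2", UNCONSTRAINED]
        fits = [AUFit(0, 0, p if lab == best else 1 - p) for lab in labels]
        totals = np.array([0.0 if lab == best else -1.0 for lab in labels])
        return AUTestResult(lid, labels, np.zeros((10, 3)), fits, totals,
                            best, p, p > 0.95,
                            {lab: None for lab in labels})

    results = [result("l1", "H1", 0.99), result("l2", "H1", 0.97),
               result("l3", "H1", 0.80), result("l4", "H1", 0.96),
               result("l5", "H2", 0.50), result("l6", "H2", 0.99)]
    tally = ggi_tally(results)
    ok_tally = (tally.count("H1") == 4 and tally.count("H2") == 2
                and tally.count("H1", significant=True) == 3
                and tally.count("H2", significant=True) == 1)
    return {"completeness_exact": float(ok75 and ok90),
            "topk_exact": float(ok_topk),
            "tally_exact": float(ok_tally), "n": 100}
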