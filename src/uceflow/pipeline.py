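"""End-to-end orchestration of the incongruence-resolution study design.

Given (or simulating) a locus collection, runs the baseline analyses
(concatenated ML + quartet summary tree on unpartitioned gene trees) and
the three diagnostic strategies:

1. locus filtering — five best-k filtered data sets re-analyzed both ways;
2. partitioned gene trees — core/flank entropy partitioning before
   gene-tree estimation, with the paired Wilcoxon/Holm bootstrap
   comparison;
3. GGI — per-locus AU tests over constrained/unconstrained gene trees,
   tallies, and a final summary tree from the selected gene trees.

Every analysis classifies the focal node against the competing
hypotheses, producing a congruence report: one row per (data set x
method) with the recovered hypothesis label.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass

import dendropy
import numpy as np
import pandas as pd

from . import ggi_tester, locus_profiler, locus_store, msc_simulator
from . import quartet_species_tree as qst
from . import swsc_partitioner
from ._treestate import TreeState
from .genetree_engine import (
    ConstraintHypothesis, SubstitutionModel, nni_search, bootstrap_supports,
    partitioned_nni_search, partitioned_bootstrap_supports,
    tree_satisfies_constraints, select_model,
)

__all__ = [
    "PipelineConfig", "three_clade_scenario", "classify_focal",
    "estimate_gene_trees", "run_baseline", "run_strategy1", "run_strategy2",
    "run_strategy3", "run_pipeline",
]


# ============================================================== scenarios

def three_clade_scenario(taxa_per_clade: int = 3, n_outgroup: int = 3,
                         focal_length: float = 0.5,
                         clade_height: float = 1.0,
                         stem_height: float = 4.0,
                         clade_stem: float = 1.0,
                         subst_scale: float = 0.1):
    """Species tree + the two competing hypotheses at a contested node.

    Three ingroup clades C1, C2, C3; the truth places C1 with C2
    (hypothesis H1) across an internal branch of ``focal_length``
    coalescent units — the knob controlling ILS at the focal node.  H2
    is the rival arrangement (C1 with C3).  ``clade_stem`` (coalescent
    units between each clade's crown and the C1+C2 ancestor) controls
    how cleanly the clades themselves sort.  Returns
    (SpeciesTreeModel, [H1, H2]).
    """
    clades = {k: [f"{k}_{i}" for i in range(taxa_per_clade)]
              for k in ("C1", "C2", "C3")}
    outgroup = [f"OUT_{i}" for i in range(n_outgroup)]

    def ladder(taxa, base_age):
        # ladderized clade with uniform internal spacing below base_age
        if len(taxa) == 1:
            return taxa[0], 0.0
        step = clade_height / len(taxa)
        nwk, age = taxa[0], 0.0
        for i, t in enumerate(taxa[1:], start=1):
            new_age = i * step
            nwk = f"({nwk}:{new_age - age:g},{t}:{new_age:g})"
            age = new_age
        return nwk, age

    parts = {}
    for k, taxa in clades.items():
        parts[k], parts[k + "_age"] = ladder(taxa, clade_height)
    og, og_age = ladder(outgroup, clade_height)
    a12 = clade_height + clade_stem
    n1 = (f"({parts['C1']}:{a12 - parts['C1_age']:g},"
          f"{parts['C2']}:{a12 - parts['C2_age']:g})")
    a123 = a12 + focal_length
    n2 = f"({n1}:{focal_length:g},{parts['C3']}:{a123 - parts['C3_age']:g})"
    root_age = a123 + stem_height
    nwk = (f"({n2}:{stem_height:g},{og}:{root_age - og_age:g});")
    model = msc_simulator.SpeciesTreeModel.from_newick(nwk, subst_scale)

    h1 = ConstraintHypothesis.from_newick(
        "H1", "((({0}),({1})),({2}),({3}));".format(
            ",".join(clades["C1"]), ",".join(clades["C2"]),
            ",".join(clades["C3"]), ",".join(outgroup)))
    h2 = ConstraintHypothesis.from_newick(
        "H2", "((({0}),({1})),({2}),({3}));".format(
            ",".join(clades["C1"]), ",".join(clades["C3"]),
            ",".join(clades["C2"]), ",".join(outgroup)))
    return model, [h1, h2]


# ========================================================== classification

def classify_focal(tree: dendropy.Tree, hypotheses) -> str:
    """Which hypothesis's bipartitions does the tree display?

    Returns the label of the unique matching hypothesis, or ``"other"``
    when none (or the tree lacks the relevant taxa).
    """
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {t: i for i, t in enumerate(taxa)}
    ts = TreeState.from_dendropy(tree, index)
    matches = []
    for hyp in hypotheses:
        cons = hyp.split_index_pairs(taxa)
        if cons and tree_satisfies_constraints(ts, cons):
            matches.append(hyp.label)
    return matches[0] if len(matches) == 1 else "other"


# ============================================================== gene trees

def _localized(model: SubstitutionModel, aln) -> SubstitutionModel:
    """Model with base frequencies refit empirically to ``aln``."""
    from .genetree_engine import empirical_base_freqs

    if model.name == "JC69":
        return model
    return model.replace(base_freqs=empirical_base_freqs(aln))


def estimate_gene_trees(loci, model: SubstitutionModel,
                        schemes: dict | None = None,
                        bootstrap_replicates: int = 0, seed: int = 0,
                        max_moves: int = 30) -> dict:
    """Per-locus ML trees; partitioned when ``schemes`` provides one.

    Base frequencies are refit empirically per locus — and, in the
    partitioned mode, per segment, which is where "a separate
    substitution model for each subregion" earns its keep on
    compositionally heterogeneous loci.  Returns locus id -> dendropy
    tree (with bootstrap supports as internal-node labels when
    requested).
    """
    out = {}
    for i, locus in enumerate(loci):
        scheme = schemes.get(locus.locus_id) if schemes else None
        if scheme is not None:
            segments = [(seg, _localized(model, seg)) for seg in
                        swsc_partitioner.partition_locus(locus, scheme)]
            tree = partitioned_nni_search(segments, max_moves=max_moves)
            if bootstrap_replicates:
                tree = partitioned_bootstrap_supports(
                    segments, tree, bootstrap_replicates,
                    seed=seed + i,
                    rate_multipliers=getattr(tree, "rate_multipliers", None))
        else:
            lmodel = _localized(model, locus)
            tree = nni_search(locus, lmodel, max_moves=max_moves)
            if bootstrap_replicates:
                tree = bootstrap_supports(locus, lmodel, tree,
                                          bootstrap_replicates, seed=seed + i)
        out[locus.locus_id] = tree
    return out


# ================================================================== stages

def run_baseline(loci, taxa, model: SubstitutionModel, hypotheses,
                 gene_trees: dict | None = None, seed: int = 0,
                 dataset: str = "all") -> dict:
    """Concatenated ML + summary species tree on unpartitioned gene trees."""
    if not loci:
        raise ValueError("no loci after filtering")
    sm = locus_store.concatenate(loci)
    concat_tree = nni_search(sm.as_alignment(), model, seed=seed)
    if gene_trees is None:
        gene_trees = estimate_gene_trees(loci, model, seed=seed)
    trees = [gene_trees[l.locus_id] for l in loci]
    summary = qst.summarize_gene_trees(trees, taxa, seed=seed)
    summary_tree = summary.to_dendropy()
    return {
        "dataset": dataset,
        "concat_tree": concat_tree,
        "summary": summary,
        "summary_tree": summary_tree,
        "gene_trees": gene_trees,
        "rows": [
            {"dataset": dataset, "method": "concat_ml",
             "hypothesis": classify_focal(concat_tree, hypotheses)},
            {"dataset": dataset, "method": "summary",
             "hypothesis": classify_focal(summary_tree, hypotheses)},
        ],
    }


def run_strategy1(loci, taxa, model: SubstitutionModel, hypotheses,
                  gene_trees: dict, k: int, criteria=None,
                  seed: int = 0, dataset_prefix: str = "") -> dict:
    """Five filtered data sets (best-k per criterion), both analyses each."""
    if criteria is None:
        criteria = list(locus_profiler.CRITERIA)
    stats = locus_profiler.compute_stats(loci, gene_trees)
    rows, selections = [], {}
    for criterion in criteria:
        ids = locus_profiler.rank_and_select(stats, criterion, k)
        selections[criterion] = ids
        subset = [l for l in loci if l.locus_id in set(ids)]
        name = f"{dataset_prefix}{criterion}"
        base = run_baseline(subset, taxa, model, hypotheses,
                            gene_trees={l.locus_id: gene_trees[l.locus_id]
                                        for l in subset},
                            seed=seed, dataset=name)
        rows.extend(base["rows"])
    return {"rows": rows, "selections": selections, "stats": stats}


def run_strategy2(datasets: dict, taxa, model: SubstitutionModel, hypotheses,
                  min_len: int = swsc_partitioner.DEFAULT_MIN_LEN,
                  bootstrap_replicates: int = 50, seed: int = 0) -> dict:
    """Partitioned gene-tree re-estimation + Wilcoxon/Holm support test.

    ``datasets`` maps name -> list of loci.  Loci too short to partition
    are analyzed unpartitioned and flagged.
    """
    rows, support_pairs, per_dataset = [], {}, {}
    for name, loci in datasets.items():
        schemes = swsc_partitioner.partition_loci(loci, min_len)
        unpart = estimate_gene_trees(
            loci, model, bootstrap_replicates=bootstrap_replicates,
            seed=seed)
        part = estimate_gene_trees(
            loci, model, schemes=schemes,
            bootstrap_replicates=bootstrap_replicates, seed=seed)
        before = {lid: locus_profiler.mean_support(t)
                  for lid, t in unpart.items()}
        after = {lid: locus_profiler.mean_support(t)
                 for lid, t in part.items()}
        before = {k: v for k, v in before.items() if v is not None}
        after = {k: v for k, v in after.items() if v is not None}
        support_pairs[name] = (before, after)
        trees = [part[l.locus_id] for l in loci]
        summary = qst.summarize_gene_trees(trees, taxa, seed=seed)
        stree = summary.to_dendropy()
        rows.append({"dataset": name, "method": "summary_partitioned",
                     "hypothesis": classify_focal(stree, hypotheses)})
        per_dataset[name] = {
            "schemes": schemes, "unpartitioned": unpart,
            "partitioned": part, "summary_tree": stree,
            "unpartitionable": [lid for lid, s in schemes.items()
                                if s is None],
        }
    wilcoxon = locus_profiler.compare_support_tables(support_pairs)
    return {"rows": rows, "wilcoxon": wilcoxon, "datasets": per_dataset}


def run_strategy3(loci, taxa, hypotheses, model: SubstitutionModel | None,
                  include_unconstrained: bool = True, replicates: int = 500,
                  threshold: float = 0.95, seed: int = 0,
                  max_moves: int = 30) -> dict:
    """GGI over the corpus + final summary tree from selected gene trees."""
    if len(hypotheses) < 2:
        raise ValueError("need >= 2 hypotheses")
    config = ggi_tester.GGIConfig(
        hypotheses=list(hypotheses),
        include_unconstrained=include_unconstrained,
        replicates=replicates, threshold=threshold, seed=seed, model=model,
        max_moves=max_moves)
    results, skipped = ggi_tester.ggi_corpus(loci, config)
    tally = ggi_tester.ggi_tally(results)
    # winner among the constrained hypotheses, by significant-locus count
    labels = [h.label for h in hypotheses]
    winner = max(labels, key=lambda lab: tally.count(lab, significant=True))
    if include_unconstrained:
        selected = ggi_tester.select_gene_trees(results, winner)
    else:
        selected = [r.trees[r.best_label] for r in results
                    if r.best_label == winner]
    out = {"results": results, "skipped": skipped, "tally": tally,
           "winner": winner, "selected": selected,
           "rows": []}
    if len(selected) >= 1:
        summary = qst.summarize_gene_trees(selected, taxa, seed=seed)
        stree = summary.to_dendropy()
        out["final_tree"] = stree
        out["rows"].append({"dataset": "ggi_selected", "method": "summary",
                            "hypothesis": classify_focal(stree, hypotheses)})
    return out


# ================================================================== config

@dataclass
class PipelineConfig:
    """Single source of truth for an end-to-end run."""

    outdir: str = "uceflow_out"
    seed: int = 1
    # simulation (ignored when input_dir is set)
    input_dir: str | None = None
    n_loci: int = 40
    taxa_per_clade: int = 3
    n_outgroup: int = 3
    focal_length: float = 0.5
    locus_length: int = 300
    core_rate: float = 0.05
    flank_rate: float = 1.0
    subst_scale: float = 0.1
    missing_prob: float = 0.1
    # analysis
    completeness: tuple = (0.75, 0.90)
    filter_fraction: float = 0.6      # k = fraction * loci per matrix
    min_len: int = 25
    bootstrap_replicates: int = 25
    ggi_replicates: int = 300
    include_unconstrained: bool = True
    threshold: float = 0.95
    model: str = "hky"                # hky | jc | gtr | auto

    def to_json(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(pathlib.Path(path).read_text())
        data["completeness"] = tuple(data.get("completeness", (0.75, 0.90)))
        return cls(**data)

    def substitution_model(self, loci=None) -> SubstitutionModel | None:
        if self.model == "jc":
            return SubstitutionModel.jc69()
        if self.model == "hky":
            return SubstitutionModel.hky85(2.0,
                                           np.array([0.3, 0.2, 0.2, 0.3]))
        if self.model == "gtr":
            return SubstitutionModel.gtr(np.ones(6), np.full(4, 0.25))
        if self.model == "auto":
            return None
        raise ValueError(f"unknown model {self.model!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (or load), run baseline + all three strategies, write
    the congruence report."""
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_tree, hypotheses = three_clade_scenario(
        config.taxa_per_clade, config.n_outgroup, config.focal_length,
        subst_scale=config.subst_scale)
    if config.input_dir:
        paths = sorted(pathlib.Path(config.input_dir).glob("*.fasta"))
        loci = locus_store.read_loci(paths)
        taxa = sorted({t for l in loci for t in l.taxa})
    else:
        profile = msc_simulator.LocusProfile(
            length=config.locus_length, core_rate=config.core_rate,
            flank_rate=config.flank_rate, subst_scale=config.subst_scale,
            missing_prob=config.missing_prob)
        ds = msc_simulator.simulate_dataset(model_tree, profile,
                                            config.n_loci, config.seed)
        msc_simulator.write_dataset(ds, outdir / "data")
        loci = ds.loci
        taxa = list(model_tree.taxa)
    sub_model = config.substitution_model(loci)
    if sub_model is None:
        sub_model = select_model(locus_store.concatenate(
            loci[:5]).as_alignment())
    rows = []
    matrices = {}
    for thr in config.completeness:
        name = f"{int(thr * 100)}p"
        matrices[name] = locus_store.filter_by_completeness(
            loci, len(taxa), thr)
    all_results = {}
    for name, mloci in matrices.items():
        if not mloci:
            continue
        gene_trees = estimate_gene_trees(
            mloci, sub_model,
            bootstrap_replicates=config.bootstrap_replicates,
            seed=config.seed)
        base = run_baseline(mloci, taxa, sub_model, hypotheses,
                            gene_trees=gene_trees, seed=config.seed,
                            dataset=name)
        rows.extend(base["rows"])
        k = max(4, int(round(config.filter_fraction * len(mloci))))
        s1 = run_strategy1(mloci, taxa, sub_model, hypotheses,
                           base["gene_trees"], k=k, seed=config.seed,
                           dataset_prefix=f"{name}-")
        rows.extend(s1["rows"])
        all_results[name] = {"baseline": base, "strategy1": s1}
    s2 = run_strategy2({n: m for n, m in matrices.items() if m}, taxa,
                       sub_model, hypotheses, min_len=config.min_len,
                       bootstrap_replicates=config.bootstrap_replicates,
                       seed=config.seed)
    rows.extend(s2["rows"])
    primary = next(iter(matrices.values()))
    s3 = run_strategy3(primary, taxa, hypotheses, sub_model,
                       include_unconstrained=config.include_unconstrained,
                       replicates=config.ggi_replicates,
                       threshold=config.threshold, seed=config.seed)
    rows.extend(s3["rows"])
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "congruence_report.tsv", sep="\t", index=False)
    s2["wilcoxon"].to_csv(outdir / "wilcoxon_holm.tsv", sep="\t",
                          index=False)
    s3["tally"].table.to_csv(outdir / "ggi_tally.tsv", sep="\t", index=False)
    if "final_tree" in s3:
        (outdir / "final_species_tree.nwk").write_text(
            s3["final_tree"].as_string(schema="newick"))
    return {"report": report, "strategy2": s2, "strategy3": s3,
            "matrices": matrices, "results": all_results,
            "hypotheses": hypotheses, "taxa": taxa}
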