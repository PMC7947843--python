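"""Multispecies-coalescent simulation of UCE-like data.

Generates (i) gene trees embedded in a species tree under the Kingman
coalescent — within each species-tree branch of length t coalescent
units (time / 2N generations), k lineages coalesce at rate k(k-1)/2 —
and (ii) locus alignments with the hallmark UCE rate architecture: a
slow conserved core flanked by regions whose substitution rate rises
linearly toward the alignment edges.  Taxon dropout emulates the
missing-data regimes that the 75p/90p completeness filters act on.

Reproducibility: every public operation takes one integer master seed;
locus ``i`` uses ``numpy.random.default_rng([seed, i])`` so any locus
can be regenerated independently.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genetree_engine import SubstitutionModel
from .locus_store import LocusAlignment, write_locus_fasta

__all__ = [
    "SpeciesTreeModel", "LocusProfile", "SyntheticDataset",
    "simulate_gene_trees", "simulate_locus_alignment", "inject_missing_taxa",
    "simulate_dataset", "random_ultrametric_tree", "write_dataset",
]


# ============================================================ species tree

class InvalidModelError(ValueError):
    pass


@dataclass
class SpeciesTreeModel:
    """Rooted binary species tree in coalescent units.

    ``subst_scale`` maps coalescent-unit branch lengths to expected
    substitutions/site (at rate multiplier 1): realistic UCE flanks sit
    around 0.02-0.2 substitutions/site per coalescent unit.
    """

    tree: dendropy.Tree
    subst_scale: float = 0.1

    def __post_init__(self):
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(leaves) < 3:
            raise InvalidModelError("species tree needs >= 3 taxa")
        if len(set(leaves)) != len(leaves):
            raise InvalidModelError("duplicate taxon labels")
        for nd in self.tree.preorder_node_iter():
            kids = nd.num_child_nodes()
            if kids not in (0, 2):
                raise InvalidModelError("species tree must be binary")
            if nd.edge.length is not None and nd.edge.length < 0:
                raise InvalidModelError("negative branch length")
        self.taxa = tuple(sorted(leaves))

    @classmethod
    def from_newick(cls, newick: str, subst_scale: float = 0.1):
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            raise InvalidModelError(f"bad species-tree newick: {exc}") \
                from exc
        return cls(tree, subst_scale)

    def node_ages(self) -> dict:
        """Age of each node above the leaves (leaves at age 0)."""
        ages = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                ages[nd] = 0.0
            else:
                ages[nd] = max(ages[ch] + (ch.edge.length or 0.0)
                               for ch in nd.child_nodes())
        return ages


def random_ultrametric_tree(taxa, seed: int, height: float = 2.0,
                            subst_scale: float = 0.1) -> SpeciesTreeModel:
    """Random coalescent-shaped ultrametric species tree, rescaled to
    total ``height`` coalescent units."""
    rng = np.random.default_rng(seed)
    taxa = list(taxa)
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(t)
        nd.age_ = 0.0
        nodes.append(nd)
    t_now = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t_now += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age_ = t_now
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t_now - a.age_
        b.edge.length = t_now - b.age_
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    scale = height / t_now
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return SpeciesTreeModel(tree, subst_scale)


# ============================================================== gene trees

def simulate_gene_trees(model: SpeciesTreeModel, n_genes: int,
                        seed: int) -> list[dendropy.Tree]:
    """Coalescent gene trees embedded in the species tree.

    Branch lengths are in coalescent units; trees are rooted and span
    all species-tree taxa.  Deterministic for a fixed seed; gene ``i``
    draws from ``default_rng([seed, i])``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    ages = model.node_ages()
    out = []
    for g in range(n_genes):
        rng = np.random.default_rng([seed, g])
        out.append(_one_gene_tree(model, ages, rng))
    return out


def _one_gene_tree(model, ages, rng):
    ns = model.tree.taxon_namespace
    # lineage = (dendropy.Node of the gene tree, height)
    active: dict = {}
    for nd in model.tree.postorder_node_iter():
        if nd.is_leaf():
            g = dendropy.Node()
            g.taxon = nd.taxon
            active[nd] = [(g, 0.0)]
            continue
        lineages = []
        for ch in nd.child_nodes():
            lineages.extend(_coalesce_in_branch(
                active.pop(ch), ages[ch], ch.edge.length or 0.0, rng))
        active[nd] = lineages
    # root branch: coalesce remaining lineages to one
    root_lineages = active[model.tree.seed_node]
    root_lineages = _coalesce_in_branch(root_lineages,
                                        ages[model.tree.seed_node],
                                        np.inf, rng)
    top, height = root_lineages[0]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = top
    tree.is_rooted = True
    return tree


def _coalesce_in_branch(lineages, t_start, t_len, rng):
    """Kingman coalescent among ``lineages`` over a branch of t_len units."""
    t_now = t_start
    t_end = t_start + t_len
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t_now + wait >= t_end:
            break
        t_now += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a[0])
        parent.add_child(b[0])
        a[0].edge.length = t_now - a[1]
        b[0].edge.length = t_now - b[1]
        lineages = [l for idx, l in enumerate(lineages)
                    if idx not in (i, j)] + [(parent, t_now)]
    return lineages


# ================================================================ alignments

@dataclass
class LocusProfile:
    """Rate architecture and model for one simulated UCE-like locus.

    The core occupies ``core_fraction`` of the sites, centered; its rate
    multiplier must be below every flank multiplier (cores are
    conserved).  Flank rates jump to ``flank_rate_min`` at the core
    boundary and rise linearly to ``flank_rate`` at the alignment edge —
    the conserved core is a distinct rate regime, not the bottom of a
    continuous ramp, which is what makes the core/flank boundary a
    recoverable feature.

    Flanks may also evolve under their own substitution process
    (``flank_model``; default AT-rich with a higher transition bias),
    mirroring the compositional contrast between UCE cores and flanks
    that per-segment models are meant to absorb.  Set ``flank_model``
    to None for rate-only heterogeneity.
    """

    length: int = 600
    core_fraction: float = 1.0 / 3.0
    core_rate: float = 0.05
    flank_rate: float = 1.0
    flank_rate_min: float = 0.5
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel.hky85(
            2.0, np.array([0.28, 0.22, 0.22, 0.28])))
    flank_model: SubstitutionModel | None = field(
        default_factory=lambda: SubstitutionModel.hky85(
            4.0, np.array([0.35, 0.15, 0.15, 0.35])))
    subst_scale: float = 0.1
    missing_prob: float = 0.2

    def __post_init__(self):
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must be strictly inside (0,1)")
        if not self.core_rate < self.flank_rate_min <= self.flank_rate:
            raise ValueError("need core_rate < flank_rate_min <= flank_rate")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")

    def breakpoints(self) -> tuple[int, int]:
        """True (left, right) core boundaries, 0-based half-open."""
        core_len = int(round(self.length * self.core_fraction))
        left = (self.length - core_len) // 2
        return left, left + core_len

    def site_rates(self) -> np.ndarray:
        left, right = self.breakpoints()
        rates = np.empty(self.length)
        rates[left:right] = self.core_rate
        j = np.arange(left)
        if left:
            # site left-1 abuts the core; site 0 is the alignment edge
            frac = (j + 0.5) / left
            rates[:left] = self.flank_rate + \
                (self.flank_rate_min - self.flank_rate) * frac
        j = np.arange(self.length - right)
        if self.length - right:
            frac = (j + 0.5) / (self.length - right)
            rates[right:] = self.flank_rate_min + \
                (self.flank_rate - self.flank_rate_min) * frac
        return rates


def simulate_locus_alignment(gene_tree: dendropy.Tree, profile: LocusProfile,
                             seed: int, locus_id: str = "locus",
                             ) -> tuple[LocusAlignment, tuple[int, int]]:
    """Evolve sequences along a gene tree with the core/flank rate profile.

    Branch lengths of ``gene_tree`` are coalescent units; the effective
    branch length at site s is ``len * subst_scale * rate[s]``.
    Returns the alignment and the true breakpoints.
    """
    rng = np.random.default_rng(seed)
    rates = profile.site_rates() * profile.subst_scale
    S = profile.length
    left, right = profile.breakpoints()
    core_mask = np.zeros(S, bool)
    core_mask[left:right] = True
    flank_model = profile.flank_model or profile.model
    groups = [(core_mask, profile.model), (~core_mask, flank_model)]
    states: dict = {}
    root = gene_tree.seed_node
    root_states = np.empty(S, dtype=np.int64)
    for mask, m in groups:
        root_states[mask] = rng.choice(4, size=int(mask.sum()),
                                       p=m.base_freqs)
    states[root] = root_states
    for nd in gene_tree.preorder_node_iter():
        if nd is root:
            continue
        t = (nd.edge.length or 0.0)
        parent_states = states[nd.parent_node]
        child = np.empty(S, dtype=np.int64)
        for mask, m in groups:
            A, lam, B = m.eigen()
            E = np.exp(np.outer(rates[mask] * t, lam))          # (Sg, 4)
            probs = np.einsum("sk,ky->sy", A[parent_states[mask]] * E, B)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(int(mask.sum()))
            child[mask] = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        states[nd] = child
    bases = np.array(list("ACGT"))
    taxa, rows = [], []
    for lf in sorted(gene_tree.leaf_node_iter(),
                     key=lambda n: n.taxon.label):
        taxa.append(lf.taxon.label)
        rows.append(bases[np.minimum(states[lf], 3)])
    aln = LocusAlignment(locus_id, tuple(taxa), np.array(rows))
    return aln, profile.breakpoints()


# ================================================================= dataset

@dataclass
class SyntheticDataset:
    """Loci plus the simulation truth they were generated from."""

    loci: list[LocusAlignment]
    gene_trees: list[dendropy.Tree]
    breakpoints: list[tuple[int, int]]
    species_tree: SpeciesTreeModel

    def __post_init__(self):
        if not (len(self.loci) == len(self.gene_trees)
                == len(self.breakpoints)):
            raise ValueError("one gene tree and breakpoint pair per locus")
        taxa = set(self.species_tree.taxa)
        for locus in self.loci:
            if not set(locus.taxa) <= taxa:
                raise ValueError(
                    f"locus {locus.locus_id} has unknown taxa")


def simulate_dataset(model: SpeciesTreeModel, profile: LocusProfile,
                     n_loci: int, seed: int,
                     min_taxa: int = 4) -> SyntheticDataset:
    """Gene trees + alignments + dropout in one call (the study generator)."""
    trees = simulate_gene_trees(model, n_loci, seed)
    loci, bps = [], []
    width = max(4, len(str(n_loci)))
    for i, gt in enumerate(trees):
        aln, bp = simulate_locus_alignment(
            gt, profile, seed=np.random.default_rng([seed, i, 1]).integers(
                2**31), locus_id=f"uce-{i:0{width}d}")
        loci.append(aln)
        bps.append(bp)
    ds = SyntheticDataset(loci, trees, bps, model)
    if profile.missing_prob > 0:
        ds = inject_missing_taxa(ds, profile.missing_prob, min_taxa,
                                 seed=np.random.default_rng(
                                     [seed, 2**20]).integers(2**31))
    return ds


def inject_missing_taxa(dataset: SyntheticDataset, p_missing: float,
                        min_taxa: int = 4, seed: int = 0) -> SyntheticDataset:
    """Drop taxa from loci independently with probability ``p_missing``.

    A locus never falls below ``min_taxa`` (randomly chosen dropped taxa
    are restored if needed).  Gene-tree truth is untouched.
    """
    if not 0 <= p_missing < 1:
        raise ValueError("p_missing must be in [0, 1)")
    if min_taxa < 4:
        raise ValueError("min_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    new_loci = []
    for locus in dataset.loci:
        keep = rng.random(locus.n_taxa) >= p_missing
        if keep.sum() < min_taxa:
            dropped = np.flatnonzero(~keep)
            need = min_taxa - int(keep.sum())
            back = rng.choice(len(dropped), size=need, replace=False)
            keep[dropped[back]] = True
        kept = [t for t, k in zip(locus.taxa, keep) if k]
        new_loci.append(locus.subset_taxa(kept))
    return SyntheticDataset(new_loci, dataset.gene_trees,
                            dataset.breakpoints, dataset.species_tree)


# ==================================================================== I/O

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """FASTA per locus, newick truth trees, TSV truth tables, JSON manifest."""
    outdir = pathlib.Path(outdir)
    (outdir / "loci").mkdir(parents=True, exist_ok=True)
    for locus in dataset.loci:
        write_locus_fasta(locus, outdir / "loci" / f"{locus.locus_id}.fasta")
    with open(outdir / "true_gene_trees.nwk", "w") as fh:
        for gt in dataset.gene_trees:
            fh.write(gt.as_string(schema="newick",
                                  suppress_rooting=True).strip() + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("locus\tleft\tright\tn_taxa\n")
        for locus, (l, r) in zip(dataset.loci, dataset.breakpoints):
            fh.write(f"{locus.locus_id}\t{l}\t{r}\t{locus.n_taxa}\n")
    manifest = {
        "n_loci": len(dataset.loci),
        "taxa": list(dataset.species_tree.taxa),
        "species_tree": dataset.species_tree.tree.as_string(
            schema="newick").strip(),
        "subst_scale": dataset.species_tree.subst_scale,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2)
                                          + "\n")
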