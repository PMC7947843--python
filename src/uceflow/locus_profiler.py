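"""Per-locus filtering statistics and the partitioning-benefit test.

Implements the five locus-quality criteria used to build filtered data
sets (best-k selection per criterion):

1. average bootstrap — mean internal-branch support of the gene tree
   (higher is better);
2. clocklikeness — variance of root-to-tip path lengths after midpoint
   rooting (lower is better; 0 iff ultrametric);
3. GC proportion — (G+C)/(A+C+G+T) over all cells (lower is better);
4. nPIS — number of parsimony-informative sites (higher is better);
5. saturation — slope of a through-origin regression of uncorrected
   p-distance on patristic distance (higher slope = less saturated).

Also provides the paired one-sided Wilcoxon signed-rank comparison (with
Holm correction across data sets) used to test whether core/flank
partitioning improves gene-tree bootstrap support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .locus_store import LocusAlignment, pairwise_p_distances

__all__ = [
    "LocusStats", "CRITERIA", "gc_proportion", "count_informative_sites",
    "clocklikeness", "saturation_slope", "mean_support", "compute_stats",
    "rank_and_select", "paired_support_test", "holm_adjust",
    "compare_support_tables",
]

#: criterion name -> True if higher values are better
CRITERIA = {
    "avg_bootstrap": True,
    "clocklikeness": False,
    "gc": False,
    "npis": True,
    "saturation": True,
}


@dataclass
class LocusStats:
    locus_id: str
    avg_bootstrap: float | None = None
    clocklikeness: float | None = None
    gc: float | None = None
    npis: int | None = None
    saturation: float | None = None

    def value(self, criterion: str):
        return getattr(self, criterion)


# ------------------------------------------------------------- alignments

def gc_proportion(locus: LocusAlignment) -> float | None:
    """GC fraction among unambiguous bases; None if there are none."""
    counts = {b: (locus.matrix == b).sum() for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return None
    return (counts["G"] + counts["C"]) / total


def count_informative_sites(locus: LocusAlignment) -> int:
    """Sites with >= 2 unambiguous states each in >= 2 sequences."""
    M = locus.matrix
    counts = np.stack([(M == b).sum(axis=0) for b in "ACGT"])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


# ------------------------------------------------------------------ trees

def _root_to_tip_depths(tree: dendropy.Tree) -> np.ndarray:
    tree.calc_node_root_distances(
        return_leaf_distances_only=False)
    return np.array([lf.root_distance for lf in tree.leaf_node_iter()],
                    float)


def clocklikeness(tree: dendropy.Tree, rooting: str = "midpoint") -> float:
    """Population variance of root-to-tip path lengths.

    ``rooting="midpoint"`` (default) measures depths from the midpoint
    of the longest tip-to-tip path; ``"given"`` keeps the tree's current
    root.  Zero iff the (so rooted) tree is ultrametric.

    The midpoint depths come straight from the patristic matrix: with
    (a, b) the maximally distant pair at distance D, a leaf x at
    distance c_x off the a-b path, projecting onto it q_x from a, its
    depth is c_x + |q_x - D/2|.  (No re-rooted tree is built; dendropy's
    ``reroot_at_midpoint`` mishandles midpoints falling on a node.)
    """
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None and e.length is None:
            raise ValueError("tree has missing branch lengths")
    if rooting == "given":
        work = tree.clone(depth=1)
        return float(np.var(_root_to_tip_depths(work)))
    if rooting != "midpoint":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    a, b = np.unravel_index(np.argmax(D), D.shape)
    span = D[a, b]
    off_path = (D[a] + D[b] - span) / 2.0
    along = D[a] - off_path
    depths = off_path + np.abs(along - span / 2.0)
    return float(np.var(depths))


def saturation_slope(locus: LocusAlignment, tree: dendropy.Tree) -> float:
    """Through-origin OLS slope of p-distance on patristic distance.

    slope = sum(x*y) / sum(x^2) over all taxon pairs; pairs with no
    overlapping unambiguous sites are skipped.  Returns 0 when all
    patristic distances vanish (such a locus ranks last).
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in locus.taxa if t not in taxa]
    if missing:
        raise ValueError(f"tree lacks taxa {missing}")
    P = pairwise_p_distances(locus)
    sxy = sxx = 0.0
    for i in range(locus.n_taxa):
        for j in range(i + 1, locus.n_taxa):
            if math.isnan(P[i, j]):
                continue
            x = pdm.patristic_distance(taxa[locus.taxa[i]],
                                       taxa[locus.taxa[j]])
            sxy += x * P[i, j]
            sxx += x * x
    if sxx == 0.0:
        return 0.0
    return sxy / sxx


def mean_support(tree: dendropy.Tree) -> float | None:
    """Mean internal-branch support on the 0-100 scale.

    Supports are read from internal-node labels (the newick convention
    used by the bootstrap writer).  None when no internal branch carries
    a support value.
    """
    vals = []
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        label = nd.label
        if label is None and nd.edge.label is not None:
            label = nd.edge.label
        if label is not None:
            try:
                vals.append(float(label))
            except ValueError:
                pass
    if not vals:
        return None
    return float(np.mean(vals))


# ------------------------------------------------------------- aggregation

def compute_stats(loci, trees) -> list[LocusStats]:
    """Five statistics per locus; ``trees`` maps locus id -> gene tree
    (with supports where available)."""
    out = []
    for locus in loci:
        tree = trees.get(locus.locus_id) if trees else None
        st = LocusStats(locus.locus_id)
        st.gc = gc_proportion(locus)
        st.npis = count_informative_sites(locus)
        if tree is not None:
            st.avg_bootstrap = mean_support(tree)
            st.clocklikeness = clocklikeness(tree)
            st.saturation = saturation_slope(locus, tree)
        out.append(st)
    return out


def stats_table(stats) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": s.locus_id, "avg_bootstrap": s.avg_bootstrap,
        "clocklikeness": s.clocklikeness, "gc": s.gc, "npis": s.npis,
        "saturation": s.saturation} for s in stats])


def rank_and_select(stats, criterion: str, k: int = 600) -> list[str]:
    """Ids of the k best loci under one criterion.

    Sorted best-first; ties broken by ascending locus id; loci with a
    missing statistic are excluded from the ranking.  Raises when fewer
    than k loci have the statistic defined.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if k <= 0:
        raise ValueError("k must be positive")
    higher_better = CRITERIA[criterion]
    usable = [(s.value(criterion), s.locus_id) for s in stats
              if s.value(criterion) is not None
              and not (isinstance(s.value(criterion), float)
                       and math.isnan(s.value(criterion)))]
    if len(usable) < k:
        raise ValueError(
            f"criterion {criterion}: only {len(usable)} loci have a defined "
            f"statistic, {k - len(usable)} short of k={k}")
    sign = -1.0 if higher_better else 1.0
    usable.sort(key=lambda t: (sign * t[0], t[1]))
    return [locus_id for _, locus_id in usable[:k]]


# ---------------------------------------------------------------- testing

def paired_support_test(before, after) -> float:
    """One-sided Wilcoxon signed-rank p for 'after > before'.

    Normal approximation with continuity and tie corrections; zero
    differences dropped.  Inputs are mappings locus id -> mean support,
    paired on their shared ids.  Returns 1.0 when every difference is 0.
    """
    ids = sorted(set(before) & set(after))
    if not ids:
        raise ValueError("no shared locus ids")
    x = np.array([after[i] for i in ids], float)
    y = np.array([before[i] for i in ids], float)
    d = x - y
    if np.all(d == 0):
        return 1.0
    res = wilcoxon(x, y, alternative="greater", zero_method="wilcox",
                   correction=True, method="approx")
    return float(res.pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family order preserved)."""
    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def compare_support_tables(datasets: dict) -> pd.DataFrame:
    """Wilcoxon/Holm table across a family of data sets.

    ``datasets`` maps name -> (before, after) support mappings; returns
    one row per data set with raw and Holm-adjusted p-values.
    """
    names = list(datasets)
    raw = [paired_support_test(*datasets[n]) for n in names]
    adj = holm_adjust(raw)
    return pd.DataFrame({"dataset": names, "p_raw": raw, "p_holm": adj})
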