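"""Quartet-based summary species-tree estimation.

Gene trees are summarized into an unrooted species tree by maximizing
the number of induced gene-tree quartets the species topology agrees
with — the maximum-quartet-support criterion that makes summary methods
statistically consistent under the multispecies coalescent.  Around each
internal branch the three quartet-arrangement frequencies (q1, q2, q3)
are reported together with a support value and the coalescent-unit
branch length d = -ln(1.5 * (1 - q1)), the MSC inversion of the expected
concordant-quartet frequency q1 = 1 - (2/3) e^(-d).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.special import betainc, betaln

from ._treestate import TreeState, nj_topology

__all__ = [
    "QuartetTable", "BranchQuartetSupport", "SpeciesTreeResult",
    "quartet_table", "quartet_score", "search_species_tree",
    "branch_support", "root_with_outgroup", "coalescent_branch_length",
    "D_CAP",
]

#: Cap on coalescent branch lengths as q1 -> 1 (the log diverges).
D_CAP = 9.0


# ============================================================== distances

def _topo_distance_matrix(tree: dendropy.Tree, index: dict[str, int],
                          n: int):
    """Unit-branch-length leaf distances; (D, present) with absent taxa
    marked in ``present``."""
    nodes = list(tree.preorder_node_iter())
    nid = {id(nd): i for i, nd in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for nd in nodes:
        for ch in nd.child_nodes():
            a, b = nid[id(nd)], nid[id(ch)]
            adj[a].append(b)
            adj[b].append(a)
    # NB a degree-2 root merely subdivides one edge; unit distances are
    # still a tree metric of the unrooted topology, so no correction.
    D = np.full((n, n), np.inf)
    present = np.zeros(n, bool)
    leaf_ids = {}
    for lf in tree.leaf_node_iter():
        ti = index.get(lf.taxon.label)
        if ti is not None:
            leaf_ids[ti] = nid[id(lf)]
            present[ti] = True
    for ti, start in leaf_ids.items():
        dist = {start: 0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        for tj, end in leaf_ids.items():
            D[ti, tj] = dist[end]
    return D, present


def _state_distance_matrix(ts: TreeState) -> np.ndarray:
    n = ts.n
    D = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v in ts.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        for other in range(n):
            D[leaf, other] = dist[other]
    return D


# ================================================================= table

@dataclass
class QuartetTable:
    """Counts of the three unrooted topologies for every 4-taxon set.

    Row ``i`` corresponds to ``quartets[i] = (a, b, c, d)`` (sorted);
    columns to the pairings ab|cd, ac|bd, ad|bc.  A gene tree missing
    any member of a quartet contributes nothing to that row.
    """

    taxa: tuple[str, ...]
    quartets: np.ndarray          # (Q, 4) int
    counts: np.ndarray            # (Q, 3) int
    n_gene_trees: int = 0

    def row_of(self, quartet) -> int:
        key = tuple(sorted(quartet))
        if not hasattr(self, "_rowmap"):
            self._rowmap = {tuple(q): i
                            for i, q in enumerate(map(tuple, self.quartets))}
        return self._rowmap[key]


def _quartet_sums(D: np.ndarray, quartets: np.ndarray):
    a, b, c, d = (quartets[:, k] for k in range(4))
    s = np.stack([D[a, b] + D[c, d], D[a, c] + D[b, d],
                  D[a, d] + D[b, c]], axis=1)
    return s


def quartet_table(gene_trees, taxa) -> QuartetTable:
    """Tally induced quartet topologies across gene trees.

    The displayed pairing of a quartet is recognized by the four-point
    condition on unit-branch-length path distances.
    """
    taxa = tuple(taxa)
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    quartets = np.array(list(itertools.combinations(range(n), 4)), int)
    counts = np.zeros((len(quartets), 3), int)
    for gt in gene_trees:
        D, present = _topo_distance_matrix(gt, index, n)
        ok = present[quartets].all(axis=1)
        if not ok.any():
            continue
        s = _quartet_sums(D, quartets[ok])
        order = np.sort(s, axis=1)
        resolved = order[:, 0] < order[:, 1] - 1e-9
        top = np.argmin(s, axis=1)
        rows = np.flatnonzero(ok)[resolved]
        np.add.at(counts, (rows, top[resolved]), 1)
    return QuartetTable(taxa, quartets, counts, len(list(gene_trees)))


def _candidate_topology_codes(ts: TreeState, quartets: np.ndarray):
    D = _state_distance_matrix(ts)
    s = _quartet_sums(D, quartets)
    return np.argmin(s, axis=1)


def quartet_score(candidate, table: QuartetTable) -> int:
    """Number of gene-tree quartets agreeing with the candidate topology."""
    if isinstance(candidate, dendropy.Tree):
        index = {t: i for i, t in enumerate(table.taxa)}
        ts = TreeState.from_dendropy(candidate, index)
    else:
        ts = candidate
    codes = _candidate_topology_codes(ts, table.quartets)
    return int(table.counts[np.arange(len(codes)), codes].sum())


# ================================================================ search

@dataclass
class BranchQuartetSupport:
    """Quartet frequencies around one internal branch."""

    split: frozenset              # taxon indices on one side
    q1: float
    q2: float
    q3: float
    m: float                      # mean informative gene trees per quartet
    support: float
    coalescent_length: float
    short_flag: bool = False      # q1 < 1/3: length clamped to 0


@dataclass
class SpeciesTreeResult:
    taxa: tuple[str, ...]
    topology: TreeState
    score: int
    branches: list[BranchQuartetSupport] = field(default_factory=list)

    def to_dendropy(self) -> dendropy.Tree:
        """Newick-ready tree: supports as internal labels, coalescent-unit
        lengths on internal edges, pendant edges lengthless."""
        universe = frozenset(range(len(self.taxa)))
        support = {b.split if 0 in b.split else universe - b.split:
                   round(b.support, 4) for b in self.branches}
        lengths = {frozenset((b.split, universe - b.split)):
                   b.coalescent_length for b in self.branches}
        tree = self.topology.to_dendropy(list(self.taxa), support=support)
        index = {t: i for i, t in enumerate(self.taxa)}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.is_leaf():
                nd.edge.length = None
                continue
            side = frozenset(index[lf.taxon.label] for lf in nd.leaf_iter())
            nd.edge.length = lengths.get(frozenset((side, universe - side)))
        return tree


def search_species_tree(table: QuartetTable, seed: int = 0,
                        n_restarts: int = 5,
                        exhaustive_max: int = 8) -> SpeciesTreeResult:
    """Maximum-quartet-score species topology.

    Exhaustive over all unrooted topologies for small taxon sets
    (n <= ``exhaustive_max``); otherwise NNI hill climbing from an
    NJ-style start on quartet-discordance distances plus seeded random
    restarts.
    """
    n = len(table.taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    if n <= exhaustive_max:
        best, best_score = None, -1
        for ts in TreeState.enumerate_topologies(n):
            sc = quartet_score(ts, table)
            if sc > best_score:
                best, best_score = ts, sc
        return SpeciesTreeResult(table.taxa, best, best_score)
    rng = np.random.default_rng(seed)
    starts = [nj_topology(_quartet_distances(table))]
    starts += [TreeState.random_topology(n, rng)
               for _ in range(max(0, n_restarts - 1))]
    best, best_score = None, -1
    for ts in starts:
        sc = _hill_climb(ts, table)
        if sc > best_score:
            best, best_score = ts, sc
    return SpeciesTreeResult(table.taxa, best, best_score)


def _quartet_distances(table: QuartetTable) -> np.ndarray:
    """Pairwise 'how rarely are i,j siblings' distances for the NJ start."""
    n = len(table.taxa)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    q = table.quartets
    c = table.counts
    pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    tot = c.sum(axis=1)
    for col, (p1, p2) in enumerate(pairings):
        for (i, j) in (p1, p2):
            a, b = q[:, i], q[:, j]
            np.add.at(num, (a, b), c[:, col])
            np.add.at(den, (a, b), tot)
    num = num + num.T
    den = den + den.T
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _hill_climb(ts: TreeState, table: QuartetTable,
                max_moves: int = 200) -> int:
    score = quartet_score(ts, table)
    for _ in range(max_moves):
        best_move, best_score = None, score
        for (u, v) in ts.internal_edges():
            for (x, y) in ts.nni_moves(u, v):
                ts.apply_nni(u, v, x, y)
                sc = quartet_score(ts, table)
                ts.apply_nni(u, v, y, x)          # undo
                if sc > best_score:
                    best_move, best_score = (u, v, x, y), sc
        if best_move is None:
            break
        u, v, x, y = best_move
        ts.apply_nni(u, v, x, y)
        score = best_score
    return score


# =============================================================== supports

def coalescent_branch_length(q1: float) -> tuple[float, bool]:
    """Invert q1 = 1 - (2/3)e^-d; below 1/3 the branch clamps to 0."""
    if q1 < 1.0 / 3.0:
        return 0.0, True
    arg = 1.5 * (1.0 - q1)
    if arg <= np.exp(-D_CAP):
        return D_CAP, False
    return float(-np.log(arg)), False


def _local_pp(n1: float, n2: float, n3: float) -> float:
    """MSC posterior of the displayed resolution, uniform prior over the
    three resolutions and a flat prior on q in (1/3, 1)."""
    m = n1 + n2 + n3
    if m == 0:
        return 1.0 / 3.0
    logs = []
    for ni in (n1, n2, n3):
        a, b = ni + 1.0, m - ni + 1.0
        tail = 1.0 - betainc(a, b, 1.0 / 3.0)
        tail = max(tail, 1e-300)
        logs.append(betaln(a, b) + np.log(tail) - (m - ni) * np.log(2.0))
    logs = np.array(logs)
    w = np.exp(logs - logs.max())
    return float(w[0] / w.sum())


def branch_support(topology, gene_trees_or_table, taxa=None,
                   method: str = "freq", max_quartets: int = 100,
                   sample_threshold: int = 15,
                   seed: int = 0) -> list[BranchQuartetSupport]:
    """Quartet frequencies (q1, q2, q3), support and coalescent length
    for every internal branch.

    Quartets take one taxon from each of the four subtrees around the
    branch; they are enumerated exhaustively up to ``sample_threshold``
    taxa and sampled (``max_quartets`` per branch, seeded) above that.
    ``method`` is ``"freq"`` (support = q1) or ``"localpp"``.
    """
    if isinstance(gene_trees_or_table, QuartetTable):
        table = gene_trees_or_table
        if taxa is None:
            taxa = table.taxa
    else:
        if taxa is None:
            raise ValueError("taxa required when passing gene trees")
        table = quartet_table(gene_trees_or_table, taxa)
    taxa = tuple(taxa)
    if isinstance(topology, dendropy.Tree):
        ts = TreeState.from_dendropy(topology,
                                     {t: i for i, t in enumerate(taxa)})
    else:
        ts = topology
    rng = np.random.default_rng(seed)
    ls = ts.all_leafsets()
    out = []
    for (u, v) in sorted(ts.internal_edges()):
        a, b = sorted(w for w in ts.adj[u] if w != v)
        c, d = sorted(w for w in ts.adj[v] if w != u)
        groups = [sorted(ls[(a, u)]), sorted(ls[(b, u)]),
                  sorted(ls[(c, v)]), sorted(ls[(d, v)])]
        combos = list(itertools.product(*groups))
        if len(taxa) > sample_threshold and len(combos) > max_quartets:
            pick = rng.choice(len(combos), size=max_quartets, replace=False)
            combos = [combos[i] for i in pick]
        N = np.zeros(3)
        per_quartet_totals = []
        for (i, j, k, l) in combos:
            row = table.row_of((i, j, k, l))
            srt = sorted((i, j, k, l))
            pos = {t: p for p, t in enumerate(srt)}
            # which column corresponds to the displayed pairing ij|kl?
            pair = frozenset((pos[i], pos[j]))
            col_disp = {frozenset(p): col for col, p in enumerate(
                [(0, 1), (0, 2), (0, 3)])}[
                    pair if 0 in pair else frozenset((pos[k], pos[l]))]
            cnt = table.counts[row]
            others = [col for col in range(3) if col != col_disp]
            N[0] += cnt[col_disp]
            N[1] += cnt[others[0]]
            N[2] += cnt[others[1]]
            per_quartet_totals.append(cnt.sum())
        total = N.sum()
        if total > 0:
            q1, q2, q3 = N / total
        else:
            q1 = q2 = q3 = 1.0 / 3.0
        m = float(np.mean(per_quartet_totals)) if per_quartet_totals else 0.0
        dlen, flag = coalescent_branch_length(q1)
        if method == "freq":
            supp = q1
        elif method == "localpp":
            scale = m / total if total else 0.0
            supp = _local_pp(N[0] * scale, N[1] * scale, N[2] * scale)
        else:
            raise ValueError(f"unknown support method {method!r}")
        out.append(BranchQuartetSupport(
            split=ls[(u, v)], q1=float(q1), q2=float(q2), q3=float(q3),
            m=m, support=float(supp), coalescent_length=dlen,
            short_flag=flag))
    return out


def summarize_gene_trees(gene_trees, taxa, seed: int = 0,
                         support_method: str = "freq") -> SpeciesTreeResult:
    """Quartet table -> topology search -> per-branch supports."""
    table = quartet_table(gene_trees, taxa)
    result = search_species_tree(table, seed=seed)
    result.branches = branch_support(result.topology, table, taxa,
                                     method=support_method, seed=seed)
    return result


# ================================================================ rooting

def root_with_outgroup(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root on the branch separating the outgroup clade from the rest.

    The outgroup must be a clade of the unrooted topology; otherwise the
    conflicting taxa are reported.
    """
    og = set(outgroup)
    t = tree.clone(depth=1)
    all_taxa = {lf.taxon.label for lf in t.leaf_node_iter()}
    if not og or not og <= all_taxa:
        raise ValueError(f"outgroup not a subset of the tree's taxa: "
                         f"{sorted(og - all_taxa)}")
    below: dict = {}
    target = None
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = {nd.taxon.label}
        else:
            below[nd] = set().union(*(below[ch] for ch in nd.child_nodes()))
        if nd.parent_node is not None and (below[nd] == og or
                                           below[nd] == all_taxa - og):
            target = nd
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic in the tree: {sorted(og)}")
    t.reroot_at_edge(target.edge, update_bipartitions=False)
    t.is_rooted = True
    return t


def write_branch_table(branches, taxa, path) -> None:
    import pandas as pd

    rows = []
    for b in branches:
        rows.append({
            "split": "|".join(sorted(taxa[i] for i in b.split)),
            "q1": b.q1, "q2": b.q2, "q3": b.q3, "m": b.m,
            "support": b.support, "coalescent_length": b.coalescent_length,
            "short_flag": b.short_flag,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
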