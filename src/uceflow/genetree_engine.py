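"""Maximum-likelihood gene-tree estimation.

Felsenstein pruning under JC69 / HKY85 / GTR with optional discrete-gamma
rate variation, one-branch-at-a-time branch-length optimization, NNI hill
climbing (optionally restricted by a monophyly-constraint backbone),
BIC model selection over the small model set, nonparametric bootstrap
supports, edge-linked partitioned likelihoods with per-segment rate
multipliers, and per-site log-likelihoods for downstream topology tests.

The pruning kernel works on directed-edge "messages": the conditional
likelihood of all data on one side of an edge given the state at the far
node.  Because the models are time-reversible, the same message serves
any rooting, which makes NNI candidate scoring a cheap recombination of
four cached subtree messages.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace as dc_replace

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc

from ._treestate import TreeState
from .locus_store import IUPAC_MASKS, LocusAlignment, pairwise_p_distances

__all__ = [
    "SubstitutionModel", "ConstraintHypothesis", "SiteLikelihoodMatrix",
    "TaxonMismatchError", "compress_patterns", "log_likelihood",
    "optimize_branch_lengths", "nni_search", "select_model", "bic",
    "bootstrap_supports", "partitioned_likelihood", "partitioned_nni_search",
    "per_site_log_likelihoods", "nj_start_tree", "LikelihoodEngine",
]

BL_MIN, BL_MAX = 1e-8, 10.0


class TaxonMismatchError(ValueError):
    pass


# ====================================================================== model

def _discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability gamma categories (mean-1)."""
    from scipy.stats import gamma as gamma_dist

    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Time-reversible DNA model with optional discrete-gamma rates.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT and are
    relative (GT conventionally 1).  The rate matrix is rescaled so the
    mean substitution rate is one, i.e. branch lengths are expected
    substitutions per site.
    """

    name: str
    base_freqs: np.ndarray
    exchangeabilities: np.ndarray
    gamma_alpha: float | None = None
    n_categories: int = 4
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.base_freqs = np.asarray(self.base_freqs, float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("base frequencies must be 4 positive values")
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        if self.exchangeabilities.shape != (6,) or \
                np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities")

    # ------------------------------------------------------------- factories
    @classmethod
    def jc69(cls, gamma_alpha=None):
        return cls("JC69", np.full(4, 0.25), np.ones(6), gamma_alpha)

    @classmethod
    def hky85(cls, kappa: float = 2.0, base_freqs=None, gamma_alpha=None):
        if base_freqs is None:
            base_freqs = np.full(4, 0.25)
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY85", np.asarray(base_freqs, float), ex, gamma_alpha)

    @classmethod
    def gtr(cls, exchangeabilities, base_freqs, gamma_alpha=None):
        return cls("GTR", np.asarray(base_freqs, float),
                   np.asarray(exchangeabilities, float), gamma_alpha)

    def replace(self, **kw) -> "SubstitutionModel":
        kw.setdefault("_eigen", None)
        return dc_replace(self, **kw)

    # ---------------------------------------------------------------- kernel
    def q_matrix(self) -> np.ndarray:
        pi = self.base_freqs
        r = self.exchangeabilities
        R = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(idx):
            R[i, j] = R[j, i] = r[k]
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigen(self):
        """(A, lam, B) with P(t) = A @ diag(exp(lam t)) @ B."""
        if self._eigen is None:
            pi = self.base_freqs
            sq = np.sqrt(pi)
            Q = self.q_matrix()
            S = (Q * sq[:, None]) / sq[None, :]
            lam, V = np.linalg.eigh((S + S.T) / 2.0)
            A = V / sq[:, None]
            B = V.T * sq[None, :]
            self._eigen = (A, lam, B)
        return self._eigen

    def category_rates(self) -> np.ndarray:
        if self.gamma_alpha is None:
            return np.ones(1)
        return _discrete_gamma_rates(self.gamma_alpha, self.n_categories)

    def transition_matrices(self, t: float) -> np.ndarray:
        """P over categories: shape (C, 4, 4)."""
        A, lam, B = self.eigen()
        rates = self.category_rates()
        E = np.exp(np.outer(rates * t, lam))            # (C, 4)
        P = np.einsum("xk,ck,ky->cxy", A, E, B)
        return np.clip(P, 0.0, None)

    @property
    def n_free_params(self) -> int:
        k = 0
        if self.name != "JC69":
            k += 3                                       # base frequencies
        if self.name == "HKY85":
            k += 1
        elif self.name == "GTR":
            k += 5
        if self.gamma_alpha is not None:
            k += 1
        return k


def empirical_base_freqs(locus: LocusAlignment) -> np.ndarray:
    counts = np.array([(locus.matrix == b).sum() for b in "ACGT"], float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = np.maximum(counts, 1.0)                      # avoid zero freqs
    return counts / counts.sum()


# ================================================================== patterns

def compress_patterns(locus: LocusAlignment):
    """Unique site patterns, their weights, and the site->pattern index.

    ``sum(weights) == n_sites`` and the original alignment is recovered
    as ``patterns[:, inverse]``.
    """
    cols = locus.matrix.T  # (S, n)
    view = np.array(["".join(c) for c in cols])
    uniq, inverse, counts = np.unique(view, return_inverse=True,
                                      return_counts=True)
    patterns = np.array([list(u) for u in uniq], dtype="U1").T  # (n, P)
    return patterns, counts.astype(float), inverse


def _tip_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, P, 4) indicator partials from IUPAC codes."""
    n, P = patterns.shape
    out = np.empty((n, P, 4))
    for i in range(n):
        for p in range(P):
            mask = IUPAC_MASKS.get(patterns[i, p].upper(), 0b1111)
            out[i, p] = [(mask >> b) & 1 for b in range(4)]
    return out


# =================================================================== engine

class _Block:
    """One data partition: patterns + model + rate multiplier."""

    __slots__ = ("tips", "weights", "inverse", "model", "mult", "n_sites")

    def __init__(self, locus: LocusAlignment, model: SubstitutionModel,
                 mult: float = 1.0):
        patterns, self.weights, self.inverse = compress_patterns(locus)
        self.tips = _tip_partials(patterns)
        self.model = model
        self.mult = mult
        self.n_sites = locus.n_sites

    @property
    def n_patterns(self):
        return self.tips.shape[1]


class LikelihoodEngine:
    """Pruning likelihoods for one locus (one or several partitions).

    All partitions share the taxon set and the tree; each has its own
    substitution model and a rate multiplier scaling the shared branch
    lengths (the edge-linked proportional model).
    """

    def __init__(self, blocks: list[_Block], taxa: tuple[str, ...]):
        self.blocks = blocks
        self.taxa = tuple(taxa)
        self.n = len(taxa)
        self.index = {t: i for i, t in enumerate(taxa)}

    # ------------------------------------------------------------- builders
    @classmethod
    def for_locus(cls, locus: LocusAlignment,
                  model: SubstitutionModel) -> "LikelihoodEngine":
        return cls([_Block(locus, model)], locus.taxa)

    @classmethod
    def partitioned(cls, segments, rate_multipliers=None) -> "LikelihoodEngine":
        """``segments``: list of (LocusAlignment, SubstitutionModel)."""
        taxa = segments[0][0].taxa
        for seg, _ in segments[1:]:
            if seg.taxa != taxa:
                raise TaxonMismatchError("segments must share the taxon set")
        if rate_multipliers is None:
            rate_multipliers = [1.0] * len(segments)
        blocks = [_Block(seg, m, mult)
                  for (seg, m), mult in zip(segments, rate_multipliers)]
        return cls(blocks, taxa)

    @property
    def n_sites(self):
        return sum(b.n_sites for b in self.blocks)

    def base_weights(self):
        return [b.weights for b in self.blocks]

    # ------------------------------------------------------------- messages
    def _message(self, tree, u, v, msgs):
        """Message along u -> v for every block."""
        part = self._partial(tree, u, v, msgs)
        t = tree.adj[u][v]
        out = []
        for b, (arr, sc) in zip(self.blocks, part):
            P = b.model.transition_matrices(t * b.mult)   # (C,4,4)
            m = np.einsum("cyx,cpx->cpy", P, arr)
            mx = m.max(axis=(0, 2))
            mx = np.where(mx > 0, mx, 1.0)
            out.append((m / mx[None, :, None], sc + np.log(mx)))
        return out

    def _partial(self, tree, u, exclude, msgs):
        """Product of messages into u from all neighbors except ``exclude``."""
        if tree.is_leaf(u):
            out = []
            for b in self.blocks:
                C = len(b.model.category_rates())
                arr = np.broadcast_to(b.tips[u], (C,) + b.tips[u].shape)
                out.append((arr, np.zeros(b.n_patterns)))
            return out
        parts = [msgs[(w, u)] for w in tree.adj[u] if w != exclude]
        out = []
        for bi in range(len(self.blocks)):
            arr = parts[0][bi][0].copy()
            sc = parts[0][bi][1].copy()
            for other in parts[1:]:
                arr *= other[bi][0]
                sc += other[bi][1]
            out.append((arr, sc))
        return out

    def messages(self, tree: TreeState):
        post, parent = tree.rooted_orders()
        msgs = {}
        for u in post:
            p = parent[u]
            if p != -1:
                msgs[(u, p)] = self._message(tree, u, p, msgs)
        for u in post[::-1]:                              # preorder
            p = parent[u]
            for v in tree.adj[u]:
                if v != p:
                    msgs[(u, v)] = self._message(tree, u, v, msgs)
        return msgs

    # ----------------------------------------------------------- likelihood
    def _pattern_logliks(self, tree, msgs=None, root=None):
        """Per-block per-pattern log-likelihood vectors."""
        if root is None:
            root = max(tree.adj)
        if msgs is None:
            # one-off upward pass rooted at `root` is enough
            post, parent = tree.rooted_orders(root)
            msgs = {}
            for u in post:
                p = parent[u]
                if p != -1:
                    msgs[(u, p)] = self._message(tree, u, p, msgs)
        part = self._partial(tree, root, -1, msgs)
        out = []
        for b, (arr, sc) in zip(self.blocks, part):
            sl = np.einsum("cpx,x->p", arr, b.model.base_freqs) \
                / arr.shape[0]
            out.append(np.log(np.clip(sl, 1e-300, None)) + sc)
        return out

    def loglik(self, tree, msgs=None, weights=None):
        pls = self._pattern_logliks(tree, msgs)
        if weights is None:
            weights = self.base_weights()
        return float(sum(w @ pl for w, pl in zip(weights, pls)))

    def sitewise_loglik(self, tree) -> np.ndarray:
        """Per-site log-likelihoods in original site order."""
        pls = self._pattern_logliks(tree)
        return np.concatenate([pl[b.inverse]
                               for b, pl in zip(self.blocks, pls)])

    # --------------------------------------------------------- edge algebra
    def _edge_coefs(self, side_u, side_v):
        """Spectral coefficients of the likelihood as a function of the
        focal branch length, per block: lik_p(t) = sum_k a[c,p,k] e^{lam_k r_c m t}.
        """
        coefs = []
        for b, (Bu, scU), (Bv, scV) in zip(self.blocks, side_u, side_v):
            A, lam, Bm = b.model.eigen()
            U = np.einsum("cpx,xk->cpk", Bu * b.model.base_freqs, A)
            V = np.einsum("cpy,ky->cpk", Bv, Bm)
            coefs.append((U * V, scU + scV, lam, b.model.category_rates(),
                          b.mult))
        return coefs

    def _edge_pattern_logliks(self, coefs, t):
        out = []
        for a, sc, lam, rates, mult in coefs:
            E = np.exp(np.outer(rates, lam) * (t * mult))  # (C,4)
            lik = np.einsum("cpk,ck->p", a, E) / len(rates)
            out.append(np.log(np.clip(lik, 1e-300, None)) + sc)
        return out

    def _edge_loglik(self, coefs, t, weights):
        pls = self._edge_pattern_logliks(coefs, t)
        return float(sum(w @ pl for w, pl in zip(weights, pls)))

    def _optimize_edge(self, coefs, weights, xatol=1e-6):
        res = minimize_scalar(
            lambda t: -self._edge_loglik(coefs, t, weights),
            bounds=(BL_MIN, BL_MAX), method="bounded",
            options={"xatol": xatol})
        return -res.fun, float(res.x)

    def _sides(self, tree, msgs, u, v):
        return self._partial(tree, u, v, msgs), self._partial(tree, v, u, msgs)

    # --------------------------------------------------- branch optimization
    def optimize_branch_lengths(self, tree: TreeState, weights=None,
                                max_passes: int = 20, tol: float = 1e-6):
        """Cycle one-dimensional optimizations over all branches in place.

        Messages are maintained incrementally along an Euler tour so each
        branch update costs O(1) message refreshes.  Returns the final
        log-likelihood.
        """
        if weights is None:
            weights = self.base_weights()
        msgs = self.messages(tree)
        last = self.loglik(tree, msgs, weights)
        root = max(tree.adj)
        for _ in range(max_passes):
            _, parent = tree.rooted_orders(root)
            order = [u for u in tree.rooted_orders(root)[0][::-1]
                     if parent[u] != -1]                   # preorder, skip root
            self._opt_pass(tree, msgs, weights, root, parent, order)
            msgs = self.messages(tree)                     # consistency
            cur = self.loglik(tree, msgs, weights)
            if cur - last < tol:
                last = max(cur, last)
                break
            last = cur
        return last

    def _opt_pass(self, tree, msgs, weights, root, parent, preorder):
        # Optimize edge (parent[u], u) in preorder.  Both directed messages
        # across the focal edge depend on its length, so both are refreshed
        # immediately; all other messages still describe the current tree.
        for u in preorder:
            p = parent[u]
            side_p = self._partial(tree, p, u, msgs)
            side_u = self._partial(tree, u, p, msgs)
            coefs = self._edge_coefs(side_p, side_u)
            _, t = self._optimize_edge(coefs, weights)
            tree.set_length(p, u, t)
            msgs[(p, u)] = self._message(tree, p, u, msgs)
            msgs[(u, p)] = self._message(tree, u, p, msgs)

    # ------------------------------------------------------------ NNI search
    def nni_search(self, tree: TreeState, constraint_splits=None,
                   weights=None, max_moves: int = 50, tol: float = 1e-6):
        """First-improvement NNI hill climbing with branch re-optimization.

        ``constraint_splits``: iterable of frozensets (taxon-index sides of
        required bipartitions, over any subset of taxa); candidate moves
        whose topology stops displaying any of them are rejected.
        Returns the final log-likelihood; the tree is modified in place.
        """
        if weights is None:
            weights = self.base_weights()
        cons = list(constraint_splits or [])
        lnl = self.optimize_branch_lengths(tree, weights)
        moves = 0
        while moves < max_moves:
            msgs = self.messages(tree)
            leafsets = tree.all_leafsets() if cons else None
            accepted = False
            for (u, v) in sorted(tree.internal_edges()):
                a, b = sorted(w for w in tree.adj[u] if w != v)
                c, d = sorted(w for w in tree.adj[v] if w != u)
                m = {w: msgs[(w, u)] for w in (a, b)}
                m.update({w: msgs[(w, v)] for w in (c, d)})

                def side(x, y):
                    out = []
                    for bi in range(len(self.blocks)):
                        arr = m[x][bi][0] * m[y][bi][0]
                        s = m[x][bi][1] + m[y][bi][1]
                        out.append((arr, s))
                    return out

                base_coefs = self._edge_coefs(side(a, b), side(c, d))
                l0, t0 = self._optimize_edge(base_coefs, weights)
                best = (l0, None, t0)
                for x, y in ((c, b), (d, b)):
                    # exchange subtree y (at u) with subtree x (at v):
                    # u then holds {a, x}, v holds {y, other-of-cd}
                    if cons and not _move_keeps_constraints(
                            tree, leafsets, (u, v), (a, x), cons, self.n):
                        continue
                    other = d if x == c else c
                    coefs = self._edge_coefs(side(a, x), side(y, other))
                    l1, t1 = self._optimize_edge(coefs, weights)
                    if l1 > best[0] + tol:
                        best = (l1, (x, y), t1)
                if best[1] is not None:
                    x, y = best[1]
                    tree.apply_nni(u, v, y, x)
                    tree.set_length(u, v, best[2])
                    moves += 1
                    accepted = True
                    break
            if not accepted:
                break
            lnl = self.optimize_branch_lengths(tree, weights)
        lnl = self.optimize_branch_lengths(tree, weights)
        if cons and not tree_satisfies_constraints(tree, cons):
            raise RuntimeError("constraint violated after NNI search")
        return lnl

    # ----------------------------------------------------- rate multipliers
    def optimize_rate_multipliers(self, tree, fix_first: bool = False,
                                  normalize: bool = True):
        """Optimize each block's rate multiplier (branch lengths fixed)."""
        if len(self.blocks) == 1:
            return self.loglik(tree)
        for bi, b in enumerate(self.blocks):
            if fix_first and bi == 0:
                continue

            def neg(mult, bi=bi, b=b):
                old = b.mult
                b.mult = float(mult)
                val = self._block_loglik(tree, bi)
                b.mult = old
                return -val

            res = minimize_scalar(neg, bounds=(1e-3, 30.0), method="bounded",
                                  options={"xatol": 1e-4})
            b.mult = float(res.x)
        if normalize:
            w = np.array([b.n_sites for b in self.blocks], float)
            mults = np.array([b.mult for b in self.blocks])
            mean = (w * mults).sum() / w.sum()
            for b in self.blocks:
                b.mult /= mean
            for (u, v) in tree.edges():
                tree.set_length(u, v, min(tree.adj[u][v] * mean, BL_MAX))
        return self.loglik(tree)

    def _block_loglik(self, tree, bi):
        b = self.blocks[bi]
        post, parent = tree.rooted_orders()
        msgs = {}
        sub = LikelihoodEngine([b], self.taxa)
        for u in post:
            p = parent[u]
            if p != -1:
                msgs[(u, p)] = sub._message(tree, u, p, msgs)
        pl = sub._pattern_logliks(tree, msgs)[0]
        return float(b.weights @ pl)

    # ------------------------------------------------------------- bootstrap
    def bootstrap_weights(self, rng: np.random.Generator):
        """One nonparametric site resampling, as per-block pattern weights."""
        S = self.n_sites
        counts = rng.multinomial(S, np.full(S, 1.0 / S))
        out = []
        offset = 0
        for b in self.blocks:
            seg = counts[offset:offset + b.n_sites]
            out.append(np.bincount(b.inverse, weights=seg,
                                   minlength=b.n_patterns).astype(float))
            offset += b.n_sites
        return out


# ============================================================== constraints

def _split_realized(side: frozenset, rest: frozenset, tree_sides) -> bool:
    bt = side | rest
    for ts in tree_sides:
        r = ts & bt
        if r == side or r == rest:
            return True
    return False


def tree_satisfies_constraints(tree: TreeState, cons) -> bool:
    """Does the tree display every constraint bipartition?

    ``cons`` is a list of (side, rest) frozenset pairs of taxon indices;
    the union of a pair is the constraint's (possibly pruned) taxon set.
    """
    ls = tree.all_leafsets()
    sides = [ls[(u, v)] for (u, v) in tree.internal_edges()]
    return all(_split_realized(s, r, sides) for s, r in cons)


def _move_keeps_constraints(tree, leafsets, edge, new_u_side, cons, n):
    u, v = edge
    x0, x1 = new_u_side
    s0 = leafsets[(x0, u if x0 in tree.adj[u] else v)]
    s1 = leafsets[(x1, u if x1 in tree.adj[u] else v)]
    kept = [leafsets[(p, q)] for (p, q) in tree.internal_edges()
            if {p, q} != {u, v}]
    kept.append(s0 | s1)
    return all(_split_realized(s, r, kept) for s, r in cons)


@dataclass
class ConstraintHypothesis:
    """A labelled monophyly backbone for constrained tree searches.

    ``backbone`` is a (typically multifurcating) tree whose nontrivial
    bipartitions must be displayed by any conforming gene tree;
    relationships inside the backbone's clades are left free.  Taxa not
    named in the backbone are unconstrained.
    """

    label: str
    backbone: dendropy.Tree

    @classmethod
    def from_newick(cls, label: str, newick: str) -> "ConstraintHypothesis":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(label, tree)

    def backbone_taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.backbone.leaf_node_iter()]

    def split_index_pairs(self, taxa) -> list[tuple[frozenset, frozenset]]:
        """Backbone bipartitions pruned to ``taxa``, as index-set pairs."""
        taxa = list(taxa)
        index = {t: i for i, t in enumerate(taxa)}
        present = [t for t in self.backbone_taxa() if t in index]
        if len(present) < 4:
            return []
        sub = self.backbone.extract_tree_with_taxa_labels(present)
        universe = frozenset(index[t] for t in present)
        out = []
        for nd in sub.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            side = frozenset(index[lf.taxon.label]
                             for lf in nd.leaf_iter())
            rest = universe - side
            if len(side) >= 2 and len(rest) >= 2:
                out.append((side, rest))
        # deroot artifact: drop duplicate complementary splits
        uniq = []
        seen = set()
        for side, rest in out:
            key = frozenset((side, rest))
            if key not in seen:
                seen.add(key)
                uniq.append((side, rest))
        return uniq

    def is_informative_for(self, taxa) -> bool:
        return len(self.split_index_pairs(taxa)) > 0


def constrained_start_tree(taxa, constraint: ConstraintHypothesis,
                           rng: np.random.Generator,
                           branch_length: float = 0.05) -> TreeState:
    """A random binary topology displaying the constraint backbone."""
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    present = [t for t in constraint.backbone_taxa() if t in index]
    if len(present) < 3:
        return TreeState.random_topology(len(taxa), rng, branch_length)
    sub = constraint.backbone.extract_tree_with_taxa_labels(present)
    ts = TreeState.from_dendropy(sub, index, branch_length)
    _resolve_polytomies(ts, rng, branch_length)
    missing = [i for i in range(len(taxa)) if i not in
               {index[t] for t in present}]
    _attach_leaves(ts, missing, rng, branch_length)
    return ts


def _resolve_polytomies(ts: TreeState, rng, bl):
    next_id = max(ts.adj) + 1
    for u in list(ts.adj):
        while len(ts.adj[u]) > 3 or (ts.is_leaf(u) and len(ts.adj[u]) > 1):
            nbrs = sorted(ts.adj[u])
            pick = rng.choice(len(nbrs), size=2, replace=False)
            v1, v2 = nbrs[pick[0]], nbrs[pick[1]]
            w = next_id
            next_id += 1
            ts.adj[w] = {}
            for v in (v1, v2):
                t = ts.adj[u].pop(v)
                del ts.adj[v][u]
                ts.adj[w][v] = t
                ts.adj[v][w] = t
            ts.adj[u][w] = bl
            ts.adj[w][u] = bl


def _attach_leaves(ts: TreeState, leaves, rng, bl):
    next_id = max(ts.adj) + 1 if ts.adj else ts.n
    for leaf in leaves:
        edges = ts.edges()
        u, v = edges[rng.integers(len(edges))]
        w = next_id
        next_id += 1
        t = ts.adj[u].pop(v)
        del ts.adj[v][u]
        ts.adj[w] = {u: t / 2, v: t / 2, leaf: bl}
        ts.adj[u][w] = t / 2
        ts.adj[v][w] = t / 2
        ts.adj[leaf] = {w: bl}


# ============================================================ start trees

def jc_distance_matrix(locus: LocusAlignment, cap: float = 5.0) -> np.ndarray:
    """Jukes-Cantor corrected pairwise distances (capped, nan -> cap)."""
    p = pairwise_p_distances(locus)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - 4.0 * p / 3.0
        d = np.where(arg > 1e-6, -0.75 * np.log(np.clip(arg, 1e-6, None)),
                     cap)
    d = np.where(np.isnan(d), cap, d)
    np.fill_diagonal(d, 0.0)
    return np.minimum(d, cap)


def nj_start_tree(locus: LocusAlignment) -> TreeState:
    """Neighbor-joining topology on JC-corrected distances (via dendropy)."""
    if locus.n_taxa == 3:
        ts = TreeState.random_topology(3, np.random.default_rng(0))
        return ts
    d = jc_distance_matrix(locus)
    labels = [f"T{i}" for i in range(locus.n_taxa)]
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",", is_first_row_column_names=True,
        is_first_column_row_names=True)
    njt = pdm.nj_tree()
    label_map = {lab: i for i, lab in enumerate(labels)}
    ts = TreeState.from_dendropy(njt, label_map)
    for (u, v) in ts.edges():
        ts.set_length(u, v, min(max(ts.adj[u][v], 1e-4), BL_MAX))
    return ts


# ========================================================= public functions

def _tree_to_state(tree: dendropy.Tree, taxa) -> TreeState:
    index = {t: i for i, t in enumerate(taxa)}
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if labels != set(taxa):
        raise TaxonMismatchError(
            f"tree taxa do not match locus taxa: {sorted(labels ^ set(taxa))}")
    return TreeState.from_dendropy(tree, index)


def _state_to_tree(ts: TreeState, taxa, lnl=None, support=None,
                   taxon_namespace=None) -> dendropy.Tree:
    tree = ts.to_dendropy(list(taxa), taxon_namespace=taxon_namespace,
                          support=support)
    if lnl is not None:
        tree.log_likelihood = float(lnl)
    return tree


def log_likelihood(tree: dendropy.Tree, model: SubstitutionModel,
                   locus: LocusAlignment) -> float:
    """Exact pruning log-likelihood; gaps are fully ambiguous states."""
    eng = LikelihoodEngine.for_locus(locus, model)
    return eng.loglik(_tree_to_state(tree, locus.taxa))


def optimize_branch_lengths(tree: dendropy.Tree, model: SubstitutionModel,
                            locus: LocusAlignment) -> dendropy.Tree:
    eng = LikelihoodEngine.for_locus(locus, model)
    ts = _tree_to_state(tree, locus.taxa)
    lnl = eng.optimize_branch_lengths(ts)
    return _state_to_tree(ts, locus.taxa, lnl,
                          taxon_namespace=tree.taxon_namespace)


def nni_search(locus: LocusAlignment, model: SubstitutionModel,
               start: dendropy.Tree | None = None,
               constraint: ConstraintHypothesis | None = None,
               seed: int = 0, max_moves: int = 50) -> dendropy.Tree:
    """ML gene-tree search by NNI hill climbing.

    With a ``constraint``, only topologies displaying the backbone's
    bipartitions are visited, and the start tree is made conforming.
    """
    cons = constraint.split_index_pairs(locus.taxa) if constraint else []
    if start is not None:
        ts = _tree_to_state(start, locus.taxa)
        if cons and not tree_satisfies_constraints(ts, cons):
            ts = constrained_start_tree(locus.taxa, constraint,
                                        np.random.default_rng(seed))
    elif cons:
        ts = constrained_start_tree(locus.taxa, constraint,
                                    np.random.default_rng(seed))
    else:
        ts = nj_start_tree(locus)
    eng = LikelihoodEngine.for_locus(locus, model)
    lnl = eng.nni_search(ts, constraint_splits=cons, max_moves=max_moves)
    ns = start.taxon_namespace if start is not None else None
    return _state_to_tree(ts, locus.taxa, lnl, taxon_namespace=ns)


# ============================================================ model choice

def bic(loglik: float, n_params: int, n_sites: int) -> float:
    return -2.0 * loglik + n_params * math.log(n_sites)


def _fit_params(eng: LikelihoodEngine, ts: TreeState,
                model: SubstitutionModel) -> SubstitutionModel:
    """Optimize the free parameters of ``model`` on a fixed topology."""
    b = eng.blocks[0]

    def set_model(m):
        b.model = m
        return eng.loglik(ts)

    if model.name == "HKY85":
        def neg(kappa):
            return -set_model(model.replace(
                exchangeabilities=np.array([1, kappa, 1, 1, kappa, 1.0])))
        res = minimize_scalar(neg, bounds=(0.05, 50.0), method="bounded",
                              options={"xatol": 1e-3})
        model = model.replace(exchangeabilities=np.array(
            [1, res.x, 1, 1, res.x, 1.0]))
    elif model.name == "GTR":
        def neg(logr):
            ex = np.concatenate([np.exp(logr), [1.0]])
            return -set_model(model.replace(exchangeabilities=ex))
        res = minimize(neg, np.zeros(5), method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-3,
                                "fatol": 1e-4})
        model = model.replace(exchangeabilities=np.concatenate(
            [np.exp(res.x), [1.0]]))
    if model.gamma_alpha is not None:
        def neg_a(log_alpha):
            return -set_model(model.replace(gamma_alpha=float(
                np.exp(log_alpha))))
        res = minimize_scalar(neg_a, bounds=(math.log(0.05), math.log(50.0)),
                              method="bounded", options={"xatol": 1e-2})
        model = model.replace(gamma_alpha=float(np.exp(res.x)))
    set_model(model)
    return model


CANDIDATE_MODELS = ("JC69", "HKY85", "GTR")


def select_model(locus: LocusAlignment, with_gamma: bool = True,
                 candidates=CANDIDATE_MODELS) -> SubstitutionModel:
    """BIC-best model among {JC69, HKY85, GTR} x {+G, none}.

    Parameters are optimized on a fixed NJ starting topology with branch
    lengths refit once per candidate; BIC = -2 lnL + k ln(n_sites) with k
    counting substitution parameters plus branch lengths.
    """
    ts0 = nj_start_tree(locus)
    freqs = empirical_base_freqs(locus)
    n_branch = len(ts0.edges())
    best = None
    gammas = (None, 1.0) if with_gamma else (None,)
    for name in candidates:
        for alpha in gammas:
            if name == "JC69":
                model = SubstitutionModel.jc69(alpha)
            elif name == "HKY85":
                model = SubstitutionModel.hky85(2.0, freqs, alpha)
            else:
                model = SubstitutionModel.gtr(np.ones(6), freqs, alpha)
            ts = ts0.copy()
            eng = LikelihoodEngine.for_locus(locus, model)
            eng.optimize_branch_lengths(ts, max_passes=3)
            model = _fit_params(eng, ts, model)
            lnl = eng.optimize_branch_lengths(ts, max_passes=3)
            score = bic(lnl, model.n_free_params + n_branch, locus.n_sites)
            if best is None or score < best[0]:
                best = (score, model, lnl)
    return best[1]


# ============================================================== bootstrap

def bootstrap_supports(locus: LocusAlignment, model: SubstitutionModel,
                       ml_tree: dendropy.Tree, replicates: int,
                       seed: int = 0) -> dendropy.Tree:
    """Nonparametric bootstrap: site resampling + NNI re-search.

    Support for each internal branch of the ML tree is the percentage of
    replicate searches whose final topology retains that bipartition.
    """
    eng = LikelihoodEngine.for_locus(locus, model)
    return _bootstrap(eng, locus.taxa, ml_tree, replicates, seed)


_BOOT_GRID = np.geomspace(1e-7, BL_MAX, 96)


def _bootstrap(eng: LikelihoodEngine, taxa, ml_tree, replicates, seed):
    """Local-rearrangement bootstrap around every ML-tree internal branch.

    For each site resampling, the three NNI configurations of each
    internal branch compete by focal-branch-optimized log-likelihood
    (the surrounding subtrees stay at their ML estimates); a branch's
    support is the percentage of replicates its ML configuration wins.
    Because replicates differ only in pattern weights, the per-config
    likelihood curves over a branch-length grid are shared across
    replicates, so all of them are scored with a few mat-vecs.
    """
    ts = _tree_to_state(ml_tree, taxa)
    eng.optimize_branch_lengths(ts)
    rng = np.random.default_rng(seed)
    leafsets = ts.all_leafsets()
    universe = frozenset(range(ts.n))
    msgs = eng.messages(ts)
    W = np.stack([np.concatenate(eng.bootstrap_weights(rng))
                  for _ in range(replicates)])           # (R, Ptot)
    support: dict[frozenset, float] = {}
    for (u, v) in sorted(ts.internal_edges()):
        a, b = sorted(w for w in ts.adj[u] if w != v)
        c, d = sorted(w for w in ts.adj[v] if w != u)
        m = {w: msgs[(w, u)] for w in (a, b)}
        m.update({w: msgs[(w, v)] for w in (c, d)})

        def side(x, y):
            return [(m[x][bi][0] * m[y][bi][0], m[x][bi][1] + m[y][bi][1])
                    for bi in range(len(eng.blocks))]

        maxima = np.empty((3, replicates))
        for k, (su, sv) in enumerate(((side(a, b), side(c, d)),
                                      (side(a, c), side(b, d)),
                                      (side(a, d), side(b, c)))):
            coefs = eng._edge_coefs(su, sv)
            curve = np.stack(
                [np.concatenate(eng._edge_pattern_logliks(coefs, t))
                 for t in _BOOT_GRID])                   # (G, Ptot)
            maxima[k] = (curve @ W.T).max(axis=0)
        # exact ties (flat replicates) break uniformly at random
        maxima += rng.uniform(0.0, 1e-9, size=maxima.shape)
        wins = (np.argmax(maxima, axis=0) == 0).sum()
        split = leafsets[(u, v)]
        if 0 not in split:
            split = universe - split
        support[split] = 100.0 * wins / replicates
    return _state_to_tree(ts, taxa, getattr(ml_tree, "log_likelihood", None),
                          support=support,
                          taxon_namespace=ml_tree.taxon_namespace)


def _replicate_search(eng, tree, weights, max_moves: int = 10,
                      tol: float = 1e-5):
    """NNI hill climb for one bootstrap replicate.

    Branch lengths stay at their ML values except the branch created by
    an accepted rearrangement; this keeps replicate searches cheap while
    still letting weakly supported bipartitions collapse.
    """
    for _ in range(max_moves):
        msgs = eng.messages(tree)
        accepted = False
        for (u, v) in sorted(tree.internal_edges()):
            a, b = sorted(w for w in tree.adj[u] if w != v)
            c, d = sorted(w for w in tree.adj[v] if w != u)
            m = {w: msgs[(w, u)] for w in (a, b)}
            m.update({w: msgs[(w, v)] for w in (c, d)})

            def side(x, y):
                return [(m[x][bi][0] * m[y][bi][0], m[x][bi][1] + m[y][bi][1])
                        for bi in range(len(eng.blocks))]

            l0, _ = eng._optimize_edge(
                eng._edge_coefs(side(a, b), side(c, d)), weights, xatol=1e-4)
            best = (l0, None, None)
            for x in (c, d):
                other = d if x == c else c
                coefs = eng._edge_coefs(side(a, x), side(b, other))
                l1, t1 = eng._optimize_edge(coefs, weights, xatol=1e-4)
                if l1 > best[0] + tol:
                    best = (l1, x, t1)
            if best[1] is not None:
                tree.apply_nni(u, v, b, best[1])
                tree.set_length(u, v, best[2])
                accepted = True
                break
        if not accepted:
            return


# ==================================================== partitioned models

def partitioned_likelihood(segments, tree: dendropy.Tree,
                           rate_multipliers=None,
                           optimize_rates: bool = False,
                           optimize_branches: bool = False) -> float:
    """Total lnL of core/flank segments sharing one topology.

    ``segments``: list of (LocusAlignment, SubstitutionModel); each gets
    its own model and a rate multiplier on the shared branch lengths.
    """
    eng = LikelihoodEngine.partitioned(segments, rate_multipliers)
    ts = _tree_to_state(tree, eng.taxa)
    if optimize_branches:
        eng.optimize_branch_lengths(ts)
    if optimize_rates:
        return eng.optimize_rate_multipliers(ts)
    return eng.loglik(ts)


def partitioned_nni_search(segments, start: dendropy.Tree | None = None,
                           seed: int = 0, max_moves: int = 50,
                           rate_passes: int = 1) -> dendropy.Tree:
    """ML gene-tree search under the edge-linked partitioned model."""
    eng = LikelihoodEngine.partitioned(segments)
    if start is not None:
        ts = _tree_to_state(start, eng.taxa)
    else:
        # NJ on the concatenation: distances pool all segments
        from .locus_store import concatenate
        ts = nj_start_tree(concatenate([s for s, _ in segments])
                           .as_alignment())
    lnl = eng.nni_search(ts, max_moves=max_moves)
    for _ in range(rate_passes):
        eng.optimize_rate_multipliers(ts)
        lnl = eng.optimize_branch_lengths(ts)
    tree = _state_to_tree(ts, eng.taxa, lnl)
    tree.rate_multipliers = [b.mult for b in eng.blocks]
    return tree


def partitioned_bootstrap_supports(segments, ml_tree: dendropy.Tree,
                                   replicates: int, seed: int = 0,
                                   rate_multipliers=None) -> dendropy.Tree:
    eng = LikelihoodEngine.partitioned(segments, rate_multipliers)
    return _bootstrap(eng, eng.taxa, ml_tree, replicates, seed)


# ======================================================= site likelihoods

@dataclass
class SiteLikelihoodMatrix:
    """Per-tree, per-site log-likelihoods (K trees x S sites)."""

    locus_id: str
    tree_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)

    @property
    def n_trees(self):
        return self.matrix.shape[0]

    @property
    def n_sites(self):
        return self.matrix.shape[1]

    def total_logliks(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.tree_labels)


def per_site_log_likelihoods(trees, model: SubstitutionModel,
                             locus: LocusAlignment,
                             labels=None) -> SiteLikelihoodMatrix:
    """Site-likelihood matrix for a set of candidate trees.

    Row sums equal each tree's total log-likelihood (same pruning pass).
    """
    eng = LikelihoodEngine.for_locus(locus, model)
    rows = [eng.sitewise_loglik(_tree_to_state(t, locus.taxa))
            for t in trees]
    if labels is None:
        labels = [f"tree{i+1}" for i in range(len(trees))]
    return SiteLikelihoodMatrix(locus.locus_id, list(labels),
                                np.vstack(rows))
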