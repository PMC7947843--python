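"""Gene Genealogy Interrogation: per-locus topology tests via the AU test.

For each locus, gene trees are estimated under each competing hypothesis
(monophyly-constrained searches) and, in the modified mode, without any
constraint.  Site log-likelihoods of all candidate trees feed a
multiscale RELL bootstrap (resampling estimated log-likelihoods at
scales 0.5-1.4) and the approximately unbiased (AU) test: bootstrap
proportions BP(r) are transformed to z(r) = PHI^-1(1 - BP(r)) and fit by
weighted least squares to z = d*sqrt(r) + c/sqrt(r); the AU p-value is
1 - PHI(d - c).  A locus supports a hypothesis "significantly" when that
hypothesis's tree has the highest total likelihood AND its AU p exceeds
the threshold (0.95 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genetree_engine import (
    ConstraintHypothesis, LikelihoodEngine, SiteLikelihoodMatrix,
    SubstitutionModel, constrained_start_tree, nj_start_tree,
    _state_to_tree,
)
from .locus_store import LocusAlignment

__all__ = [
    "GGIConfig", "AUFit", "AUTestResult", "GGISummary", "LocusSkipped",
    "rell_bootstrap", "au_pvalue", "ggi_locus_test", "ggi_corpus",
    "ggi_tally", "select_gene_trees", "UNCONSTRAINED",
]

#: Conventional multiscale resampling factors.
DEFAULT_SCALES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)

UNCONSTRAINED = "unconstrained"


@dataclass
class GGIConfig:
    """Settings for a GGI run.

    ``include_unconstrained`` switches on the modified GGI that lets an
    unconstrained gene tree compete with the constrained ones.  The
    model is used both for the constrained searches and for the site
    likelihoods; when None, a GTR+G model with empirical base
    frequencies is fit per locus.
    """

    hypotheses: list[ConstraintHypothesis]
    include_unconstrained: bool = False
    scales: tuple = DEFAULT_SCALES
    replicates: int = 1000
    threshold: float = 0.95
    seed: int = 0
    model: SubstitutionModel | None = None
    max_moves: int = 50

    def __post_init__(self):
        if len(self.hypotheses) < 2 and not self.include_unconstrained:
            raise ValueError("need >= 2 hypotheses")
        if 1.0 not in self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive and include 1.0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class AUFit:
    c: float
    d: float
    p: float
    degenerate: bool = False


@dataclass
class AUTestResult:
    """Per-locus GGI outcome."""

    locus_id: str
    tree_labels: list[str]
    bp: np.ndarray                    # (n_scales, K)
    fits: list[AUFit]
    total_logliks: np.ndarray
    best_label: str
    best_p: float
    significant: bool
    trees: dict = field(default_factory=dict)
    site_logliks: SiteLikelihoodMatrix | None = None

    def p_values(self) -> dict:
        return {lab: f.p for lab, f in zip(self.tree_labels, self.fits)}


class LocusSkipped(Exception):
    """Locus cannot be tested (e.g. constraints collapse after pruning)."""


# ================================================================== RELL

def rell_bootstrap(matrix: SiteLikelihoodMatrix | np.ndarray, scales=None,
                   replicates: int = 1000, seed: int = 0) -> np.ndarray:
    """Multiscale bootstrap proportions from a site-lnL matrix.

    For scale r, round(r*S) sites are drawn with replacement; each
    replicate's winner is the tree with the highest resampled total lnL
    (ties broken uniformly at random).  Returns BP with shape
    (n_scales, K); rows sum to 1.
    """
    if scales is None:
        scales = DEFAULT_SCALES
    M = matrix.matrix if isinstance(matrix, SiteLikelihoodMatrix) else \
        np.asarray(matrix, float)
    K, S = M.shape
    if K < 2:
        raise ValueError("need >= 2 trees")
    if S < 10:
        raise ValueError("need >= 10 sites")
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite site log-likelihoods")
    rng = np.random.default_rng(seed)
    bp = np.zeros((len(scales), K))
    for si, r in enumerate(scales):
        m = int(round(r * S))
        counts = rng.multinomial(m, np.full(S, 1.0 / S), size=replicates)
        totals = counts @ M.T                       # (replicates, K)
        best = totals.max(axis=1, keepdims=True)
        ties = totals >= best - 1e-9
        n_tied = ties.sum(axis=1)
        winner = np.argmax(ties, axis=1)
        multi = np.flatnonzero(n_tied > 1)
        for i in multi:
            cand = np.flatnonzero(ties[i])
            winner[i] = cand[rng.integers(len(cand))]
        bp[si] = np.bincount(winner, minlength=K) / replicates
    return bp


# ================================================================ AU test

def au_pvalue(bp_tree: np.ndarray, scales=None,
              replicates: int = 1000) -> AUFit:
    """Fit the multiscale-bootstrap curve of one tree and return its AU p.

    BP values are clipped to [1/(10*replicates), 1 - 1/(10*replicates)]
    before the probit transform.  With fewer than two informative scales
    the p-value degenerates to 1 (BP == 1 everywhere) or 0 (BP == 0).
    """
    if scales is None:
        scales = DEFAULT_SCALES
    bp_tree = np.asarray(bp_tree, float)
    r = np.asarray(scales, float)
    informative = (bp_tree > 0) & (bp_tree < 1)
    if informative.sum() < 2:
        if bp_tree.mean() > 0.5:
            return AUFit(0.0, -np.inf, 1.0, degenerate=True)
        return AUFit(0.0, np.inf, 0.0, degenerate=True)
    eps = 1.0 / (10.0 * replicates)
    bp = np.clip(bp_tree, eps, 1 - eps)
    z = norm.ppf(1.0 - bp)
    # weights: inverse delta-method variance of z from binomial BP
    dens = norm.pdf(z)
    w = replicates * dens ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    d_hat, c_hat = float(beta[0]), float(beta[1])
    p = float(1.0 - norm.cdf(d_hat - c_hat))
    return AUFit(c_hat, d_hat, p)


# =================================================================== GGI

def _fit_default_model(locus: LocusAlignment) -> SubstitutionModel:
    """GTR+G with empirical frequencies, rates/alpha fit on the NJ tree."""
    from .genetree_engine import _fit_params, empirical_base_freqs

    model = SubstitutionModel.gtr(np.ones(6),
                                  empirical_base_freqs(locus),
                                  gamma_alpha=1.0)
    eng = LikelihoodEngine.for_locus(locus, model)
    ts = nj_start_tree(locus)
    eng.optimize_branch_lengths(ts, max_passes=2)
    return _fit_params(eng, ts, model)


def ggi_locus_test(locus: LocusAlignment, config: GGIConfig) -> AUTestResult:
    """Constrained (and optionally unconstrained) searches + AU test.

    Raises :class:`LocusSkipped` when a hypothesis's backbone is no
    longer informative after pruning to the locus's taxa, or when fewer
    than 4 taxa remain.
    """
    if locus.n_taxa < 4:
        raise LocusSkipped(f"{locus.locus_id}: fewer than 4 taxa")
    model = config.model or _fit_default_model(locus)
    eng = LikelihoodEngine.for_locus(locus, model)
    rng = np.random.default_rng([config.seed, abs(hash(locus.locus_id))
                                 % 2**31])
    labels, trees, states = [], [], []
    for hyp in config.hypotheses:
        cons = hyp.split_index_pairs(locus.taxa)
        if not cons:
            raise LocusSkipped(
                f"{locus.locus_id}: hypothesis {hyp.label} uninformative "
                f"after pruning")
        ts = constrained_start_tree(locus.taxa, hyp, rng)
        eng.nni_search(ts, constraint_splits=cons,
                       max_moves=config.max_moves)
        labels.append(hyp.label)
        states.append(ts)
    if config.include_unconstrained:
        ts = nj_start_tree(locus)
        eng.nni_search(ts, max_moves=config.max_moves)
        labels.append(UNCONSTRAINED)
        states.append(ts)
    rows = [eng.sitewise_loglik(ts) for ts in states]
    matrix = SiteLikelihoodMatrix(locus.locus_id, labels, np.vstack(rows))
    bp = rell_bootstrap(matrix, config.scales, config.replicates,
                        seed=rng.integers(2**31))
    fits = [au_pvalue(bp[:, k], config.scales, config.replicates)
            for k in range(len(labels))]
    totals = matrix.total_logliks()
    best_k = int(np.argmax(totals))
    best_p = fits[best_k].p
    trees = {lab: _state_to_tree(ts, locus.taxa)
             for lab, ts in zip(labels, states)}
    return AUTestResult(
        locus_id=locus.locus_id, tree_labels=labels, bp=bp, fits=fits,
        total_logliks=totals, best_label=labels[best_k], best_p=best_p,
        significant=best_p > config.threshold, trees=trees,
        site_logliks=matrix)


def ggi_corpus(loci, config: GGIConfig):
    """Run the locus test over a collection; returns (results, skipped)."""
    results, skipped = [], []
    for locus in loci:
        try:
            results.append(ggi_locus_test(locus, config))
        except LocusSkipped as exc:
            skipped.append((locus.locus_id, str(exc)))
    return results, skipped


# ================================================================ tallies

@dataclass
class GGISummary:
    """Per-hypothesis locus counts, overall and at significance."""

    table: pd.DataFrame
    n_tested: int

    def count(self, label: str, significant: bool = False) -> int:
        col = "n_significant" if significant else "n_best"
        row = self.table[self.table.hypothesis == label]
        return int(row[col].iloc[0]) if len(row) else 0


def ggi_tally(results, threshold: float | None = None) -> GGISummary:
    """Count, per hypothesis, the loci whose best tree it is.

    ``n_best`` counts all loci; ``n_significant`` only those whose best
    tree's AU p exceeds the threshold (each result's own threshold when
    ``threshold`` is None).  Percentages are relative to loci tested.
    """
    n = len(results)
    labels: list[str] = []
    for res in results:
        for lab in res.tree_labels:
            if lab not in labels:
                labels.append(lab)
    rows = []
    for lab in labels:
        best = [r for r in results if r.best_label == lab]
        if threshold is None:
            sig = [r for r in best if r.significant]
        else:
            sig = [r for r in best if r.best_p > threshold]
        rows.append({
            "hypothesis": lab,
            "n_best": len(best),
            "pct_best": 100.0 * len(best) / n if n else 0.0,
            "n_significant": len(sig),
            "pct_significant": 100.0 * len(sig) / n if n else 0.0,
        })
    return GGISummary(pd.DataFrame(rows), n)


def select_gene_trees(results, keep_hypothesis: str):
    """Best trees for the summary stage, modified-GGI selection rule.

    Keeps, per locus, the best tree when it is the unconstrained tree or
    the constrained tree of ``keep_hypothesis``; loci whose best tree
    belongs to another hypothesis are discarded.
    """
    known = {lab for r in results for lab in r.tree_labels}
    if keep_hypothesis not in known:
        raise ValueError(f"unknown hypothesis {keep_hypothesis!r}")
    kept = []
    for r in results:
        if r.best_label == keep_hypothesis or r.best_label == UNCONSTRAINED:
            kept.append(r.trees[r.best_label])
    return kept
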