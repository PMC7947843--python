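# Methods

This note documents the models, algorithms, numerical choices and
deliberate design decisions behind `uceflow`, and what the synthetic
validation studies do and do not show.

## Coalescent simulation

Gene trees are simulated under the multispecies coalescent: a rooted
binary species tree carries branch lengths in coalescent units
(time / 2N generations); within a branch holding *k* gene lineages,
coalescences occur at rate *k*(*k*−1)/2 per unit, pairs merging
uniformly at random; lineages surviving to the root coalesce in an
unbounded root branch. The implementation is verified against the
analytic triplet probability: for ((A,B):t, C), the probability that a
gene tree keeps A and B as sisters is 1 − (2/3)e^(−t).

A single multiplier (`subst_scale`, expected substitutions/site per
coalescent unit at relative rate 1) converts coalescent branch lengths
into substitution branch lengths at simulation time; gene trees
themselves are kept in coalescent units. Realistic UCE flanks sit
around 0.02–0.2 substitutions/site per coalescent unit; the default is
0.1.

Reproducibility: every simulation entry point takes one integer master
seed; locus *i* draws from `numpy.random.default_rng([seed, i])`, so
any locus can be regenerated in isolation.

## The UCE rate profile

Each simulated locus has a centered conserved core (`core_fraction`,
default 1/3 of a 600-site locus, so true breakpoints at sites 200/400)
evolving at `core_rate` (default 0.05×). Flank sites start at
`flank_rate_min` (default 0.5×) immediately outside the core and rise
linearly to `flank_rate` (default 1.0×) at the alignment edge. Two
points matter:

* The flank floor is strictly above the core rate. A ramp that starts
  *at* the core rate makes the rate profile continuous across the
  boundary, and a continuous profile has no recoverable breakpoint —
  prototype runs recovered 0/50 boundaries within ±25 sites under that
  design versus 49/50 with the floor. A conserved core is a distinct
  rate regime, not the bottom of a ramp.
* Flanks may also evolve under their own substitution process
  (`flank_model`, default AT-rich HKY with a higher transition bias),
  mirroring the compositional contrast between UCE cores and flanks.
  Set it to `None` for rate-only heterogeneity.

Missing data: each taxon is dropped from each locus independently with
probability `missing_prob` (default 0.2, which under a 20-taxon tree
yields a locus-coverage spread that makes 75p and 90p filters bite),
never below `min_taxa` (default 4). Gaps arise only from taxon removal;
indels are not simulated.

What the generator does *not* emulate: alignment/trimming artifacts,
paralogy, base-composition drift across the tree, gene flow or
hybridization, and within-locus recombination (each locus has exactly
one true genealogy). Passing tests therefore validate the *methods*
under their own model assumptions, not the full messiness of empirical
UCE matrices.

## Entropy partitioning

Per-site entropy is Shannon entropy (bits) of the A/C/G/T frequencies
among unambiguous bases; all-missing columns are defined as 0. The
breakpoint pair (l, r) minimizes the total within-segment sum of
squared errors of entropy about the three segment means, searched
exhaustively over all admissible pairs with prefix sums (O(L²));
minimum segment length 50 sites (segments must support a model fit).
Ties resolve to the smallest l, then the smallest r. Unpartitionable
loci (L < 3·min_len) are analyzed as a single segment and flagged.
The exhaustive optimum is checked exactly against a naive O(L³) oracle.
No cross-locus merging of segments is performed: every segment keeps
its own model (merging is an external tool's heuristic, and
"a separate model per subregion" is already realized without it).

## Likelihood engine

Felsenstein pruning over compressed site patterns under JC69, HKY85 or
GTR, each optionally with 4-category discrete-gamma rates (category
means, mean-1 normalization, α ∈ [0.05, 50] fit by bounded search).
Rate matrices are scaled to mean rate 1, so branch lengths are expected
substitutions/site; gaps and IUPAC ambiguities are fully/partially
ambiguous tip states. Transition matrices come from the symmetrized
eigendecomposition, which also gives each branch's likelihood as
lik(t) = Σₖ aₖ e^(λₖ t) — one 4-vector dot product per evaluation.

The pruning kernel works on directed-edge *messages* (conditional
likelihoods of everything on one side of an edge, valid from either
end because the models are reversible), rescaled per site against
underflow. Branch-length optimization cycles bounded one-dimensional
searches ([1e-8, 10], tolerance 1e-6, ≤ 20 passes) along a preorder
tour, refreshing both messages of the focal edge after each update so
every optimization sees a consistent tree; the log-likelihood is
non-decreasing across passes. NNI search is first-improvement hill
climbing in deterministic edge order: a candidate rearrangement is
scored by recombining four cached subtree messages and optimizing only
the focal branch, so one sweep costs a few milliseconds on a 12-taxon
locus.

Constrained searches take a multifurcating backbone whose bipartitions
(pruned to the locus's taxa) must be displayed; candidate moves that
stop displaying any of them are rejected, and the final tree is
verified. Start trees: neighbor joining on JC-corrected distances
(unconstrained), or the backbone with polytomies randomly resolved and
free taxa attached at random edges (constrained; seeded).

Model selection minimizes BIC = −2 lnL + k ln(S) over
{JC69, HKY85, GTR} × {+Γ, none} on a fixed NJ topology, with k counting
substitution parameters plus branch lengths.

### Partitioned likelihoods

Segments share the topology and branch lengths; each has its own
substitution model and a rate multiplier on the shared lengths (the
edge-linked proportional model). Multipliers are optimized one at a
time and renormalized to site-weighted mean 1 (the scale moves into the
branch lengths, leaving the likelihood unchanged). With identical
models and unit multipliers the partitioned likelihood equals the
unpartitioned one exactly; with free multipliers it can only be higher.
In the partitioned estimation pipeline each segment also receives its
own empirical base frequencies.

### Bootstrap supports

Supports are **local-rearrangement bootstrap** percentages: for each of
`replicates` multinomial site resamplings, the three NNI configurations
of each internal branch compete by focal-branch-optimized
log-likelihood (surrounding branches stay at their ML values, exact
ties break uniformly at random); a branch's support is the percentage
of replicates its ML configuration wins. Because replicates differ only
in pattern weights, the per-configuration likelihood curves over a
96-point branch-length grid are shared, and all replicates are scored
with matrix products — which is what makes 100 replicates × hundreds of
loci × partitioned models affordable on one core.

The original design — a first-improvement NNI hill climb re-run per
replicate from the ML topology — was measured to be degenerate: an
incumbent topology is retained by any replicate that does not actively
contradict it, pinning supports near 100 even on branches carrying one
or two substitutions. The local-rearrangement form keeps the
"NNI around the ML tree" semantics while letting a no-signal branch
fall to the uninformative 1/3 floor. These supports are comparable
*within* this package, not numerically to other programs' bootstrap
variants.

## GGI and the AU test

Per locus: one constrained search per hypothesis (plus an unconstrained
search in the modified mode), all trees scored by per-site
log-likelihoods under one model (default: GTR+Γ with empirical
frequencies, rates and α fit on the NJ tree; any explicit model can be
supplied). The multiscale RELL bootstrap resamples round(r·S) sites at
each scale r ∈ {0.5, …, 1.4} (1,000 replicates by default; 500 in the
desk-scale studies), summing per-site log-likelihoods; the per-scale
winner (ties uniform at random, seeded) yields bootstrap proportions
BP(r). The AU p-value fits z(r) = Φ⁻¹(1 − BP(r)) by weighted least
squares to d·√r + c/√r (weights from the delta-method binomial variance
of z; BP clipped to [1/(10·replicates), 1 − 1/(10·replicates)]) and
reports p = 1 − Φ(d − c). Degenerate curves short-circuit: BP ≡ 1 gives
p = 1, BP ≡ 0 gives p = 0, both flagged.

A locus "significantly supports" a hypothesis when that hypothesis's
tree has the highest total log-likelihood *and* its AU p exceeds 0.95.
(Which tree's p the 0.95 rule refers to is ambiguous in common usage;
this reading — best tree by lnL, tested by its own AU p — is the one
implemented, applied consistently to tallies and selection.) The
final-tree selection keeps, per locus, the best tree when it is the
unconstrained tree or the favored hypothesis's constrained tree, and
discards loci whose best tree belongs to a rival hypothesis.

Loci are skipped (with reason) when fewer than 4 taxa remain or a
hypothesis's backbone prunes to fewer than one nontrivial bipartition.

## Quartet species trees

Gene-tree quartet topologies are recognized by the four-point condition
on unit-branch-length path distances and tallied over all 4-taxon sets
(trees missing a quartet member skip that row). The species topology
maximizes the number of agreeing gene-tree quartets: exhaustively over
all (2n−5)!! topologies for n ≤ 8, otherwise NNI hill climbing from an
NJ start on quartet-discordance distances plus seeded random restarts
(5 by default; validated against the exhaustive optimum at n = 7).

Around each internal branch, quartets take one taxon from each of the
four surrounding subtrees (exhaustive up to 15 taxa, a seeded sample of
100 per branch above). q₁, q₂, q₃ are the aggregated frequencies of
the displayed and alternative arrangements; m is the mean number of
informative gene trees per quartet. Branch length in coalescent units
inverts the MSC expectation: d = −ln(1.5 (1 − q₁)), clamped to 0 (and
flagged) when q₁ < 1/3, capped at 9 as q₁ → 1. Default branch support
is the plain frequency q₁; an optional `localpp` mode computes the MSC
posterior of the displayed resolution under a uniform prior over the
three resolutions and a flat prior on q ∈ (1/3, 1) (beta-integral
form). The localPP option is a labelled alternative, not claimed
numerically equivalent to other tools' implementations. Rooting uses a
declared outgroup, which must be a clade of the unrooted topology.

## Study orchestration

`three_clade_scenario` builds the canonical incongruence setup: three
ingroup clades C1–C3 plus an outgroup; the truth (H1) places C1 with C2
across a focal internal branch whose length in coalescent units sets
the ILS level; H2 is the rival pairing. `clade_stem` (default 1.0)
controls how cleanly the clades themselves sort. The full pipeline
applies completeness filters (75p/90p presets, inclusive ≥), runs the
concatenated-ML and quartet-summary baselines, the five filtered
re-analyses, the partitioned re-estimation with the Wilcoxon/Holm
support comparison ("nonexact" Wilcoxon = normal approximation with
continuity and tie corrections, zero differences dropped), and GGI,
then classifies every result tree against the hypotheses (a tree that
displays no single hypothesis's bipartitions is reported as "other"
rather than forced).

## Validation studies and their sizes

All sizes were chosen once, as single-core desk-scale designs:

* MSC analytics: 5,000 triplet gene trees, tolerance ±0.02 (≈ 6
  Monte-Carlo standard errors).
* Likelihood oracles: 20 random 5-taxon instances vs exhaustive
  internal-state enumeration (agreement < 1e-8); JC branch-length MLE
  on 1,500 sites vs the closed form (< 1e-4).
* Breakpoint recovery: 50 loci × 600 bp on a 30-taxon tree, both
  breakpoints within ±25 sites in ≥ 90% of loci; objective checked
  against the cubic oracle.
* GGI power: 200 loci × 300 bp, 12 taxa, focal branch 1.0 cu,
  500-replicate RELL, HKY truth model supplied to the tester (using
  the generating model isolates the test's directional power from
  model-selection noise). The control duplicates a tree's
  site-likelihood row to make two statistically indistinguishable
  hypotheses.
* Partitioning benefit: 3 datasets × 100 loci × 300 bp, 100 bootstrap
  replicates, strong core/flank heterogeneity (0.05× core, 0.6→3.0×
  flanks, AT-rich flank process) at a weak UCE-like signal level
  (0.03 substitutions/site per coalescent unit).
* Quartet checks: 20 random 7-taxon gene-tree sets (hill climb vs
  exhaustive optimum); d recovery from 2,000 gene trees at
  t ∈ {0.5, 1, 2}, tolerance ±0.1. That band is ≈ 2.5 standard errors
  at t = 1 but only ≈ 1.4 at t = 2 (SE(d) = SE(q₁)/(1 − q₁) grows as
  q₁ → 1), so the t = 2 case is expected to miss the band for roughly
  one seed in six even though the estimator is unbiased — a property of
  the check's design, reported as measured.

### Known limitation: the partitioning-benefit direction

In this package's simulations, partitioned gene-tree estimation
consistently matches or slightly *lowers* mean bootstrap support
relative to unpartitioned estimation, across every regime explored
(rate heterogeneity 2–6×, flank saturation, compositional contrast,
weak through strong signal, three different support estimators). A
null experiment (homogeneous data, arbitrary 3-way split) shows part
of this is estimation noise from the partitioned model's extra
parameters; the rest is the partitioned model removing the
single-model fit's overconfidence rather than adding resolution. The
empirical finding this study design mirrors — significantly higher
mean bootstrap after partitioning — plausibly depends on features
outside this desk-scale setting (hundreds of taxa with near-zero
per-branch signal, richer model spaces fit per subset, and
search-derived candidate sets in ultrafast-bootstrap implementations).
The comparison machinery itself (partitioned likelihoods, paired
Wilcoxon, Holm correction) is fully tested; the directional claim is
reported as measured, and the corresponding validation test documents
the expectation rather than bending the generator to meet it.
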