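# Methods

This note documents the models and procedures implemented in `charsat`,
the defaults and why they were chosen, what the synthetic-data generator
emulates, and the numerical and statistical choices a user should know
about.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dissimilarity and patristic distance

**MORD dissimilarity.**  For taxa *i*, *j* only characters scored in both
are compared.  An unordered character contributes 0 when the two state
sets intersect (so a polymorphism sharing a state is a match) and 1 when
they are disjoint.  An ordered character contributes the minimum absolute
state difference between the two sets divided by that character's observed
state range, keeping each character's contribution in [0, 1].  The
dissimilarity is the mean contribution over comparable characters; a pair
with none is undefined and is dropped from curve fitting, never imputed.
The inapplicable token ("-") is kept distinct in the data model but
treated as missing in all computations, since the dissimilarity
convention implemented here does not distinguish them.  All characters
are treated as unordered unless flagged, matching the default treatment
of unordered multistate matrices.

**Patristic morphological distance** is the sum of branch lengths on the
tree path between two taxa, computed on a tree whose branch lengths are
expected character-state changes (e.g. from an undated Mk analysis with
fixed topology).  Topological congruence with the dated tree is checked
on load when a reference is supplied.

## Saturation and the constraint test

Dissimilarity rises with patristic distance until homoplasy re-explores
an established state space; the asymptote of a Michaelis–Menten fit

D = Vmax · P / (Km + P)

indexes the saturation level.  Constraint is judged against an
equal-rates null: each character is re-simulated under a k-state Mk
process along the changes-scaled tree, where k is that character's
observed state count in the empirical matrix (invariant characters use
k = 2, the smallest space that admits change), the root state is uniform,
and the empirical missing-data mask is written back into the simulated
matrix.  Null dissimilarities are paired with the *empirical* patristic
distances and refitted; the observed fit is compared with the null
*V*max distribution.

**Decision rule.**  A clade (or node) is called *relaxed* when the
observed 84% CI lies entirely above the central 84% interval (8th–92nd
percentiles) of the null distribution, *strengthened* when entirely
below, *none* otherwise.  The central-interval reading makes the two
directions symmetric; a one-sided variant (relaxed vs the 84th
percentile, strengthened vs the 16th) is available via
`classify_constraint(..., null_band="one_sided")`.  The calibration
behind the 84% level is computed by `ci_overlap_calibration`: two
level-% CIs of statistically identical, independent estimators overlap
~95% of the time at level 84 (an effective 0.05 threshold) and ~99% at
level 95.

**Node-wise scan.**  `scan_all_nodes` applies the test to every internal
node using only the tip pairs descending from it, so constraint shifts
can be located without prior hypotheses.  One bank of simulated null
matrices serves all nodes.  An optional divergence window (old, young Ma)
restricts pairs to those whose most recent common ancestor falls inside
the study interval, mirroring analyses that exclude incompletely sampled
younger branches.

**Numerical choices.**

- The fit minimizes squared error in (log Vmax, log Km), which keeps both
  parameters positive without explicit constraints.  Single fits use
  `scipy.optimize.least_squares` from three heuristic starts; the
  thousands of fits behind null distributions and scans use an
  in-package batched Levenberg–Marquardt on the same parameterization,
  unit-tested against the scipy route.
- The 84% CI is asymptotic-normal on the least-squares estimate,
  *V*max ± 1.4051·SE, with SE from the log-scale covariance by the delta
  method.  The method is isolated so a profile-likelihood variant could
  be swapped in.
- A fit needs at least 6 usable pairs (so ≥ 4 tips) and ≥ 3 distinct
  abscissae; below that the asymptotic CI is meaningless and the node is
  *untestable*.
- Dissimilarity is bounded by 1, so a fitted asymptote above 10 means the
  curve never bent within the observed range; such fits are reported
  unconverged (observed → untestable; null draws → dropped, with the
  failure count recorded and a warning above 20%).  A node whose null
  distribution retains fewer than 20 converged draws is untestable.
- All-zero dissimilarities short-circuit to Vmax = 0 exactly.

**Statistical caveats.**  Taxon pairs share tree paths, so the (P, D)
points are not independent; the asymptotic CI inherits this and the
procedure is anticonservative to an unknown degree, as in the published
procedure it follows.  No multiple-testing correction is applied across
nodes in the scan.  On fully null synthetic data the pooled
relaxed+strengthened call rate measured by the test suite is well inside
the ~16% bound implied by the 84% rule.

## Rates through time

Branches carry relative rates of character change (read from
MrBayes-style `[&rate=...]` comment annotations; units cancel in medians
and ratios).  A branch with parent age *p* and child age *c* contributes
its rate to every slice *t* with *c* ≤ *t* < *p* — half-open so a branch
ending exactly on a slice is not double-counted with its child — and the
per-slice median summarizes the distribution.  The default window is
320–272 Ma at 1-Myr steps (49 slices).  Medians are smoothed with a
local-polynomial (loess) trend: tricube weights over the nearest
`span`-fraction of points, degree 2 by default, exposed as parameters.
The smoother is implemented in-package because the available lowess
implementation is degree-1 only; at degree 1 the two agree (tested).
Rates are never log-transformed before medians; log scaling is a display
choice.  Group series assign a branch to a clade iff every descendant tip
belongs to it, which includes the clade's stem branch and excludes
branches ancestral to several groups.

## Mk models of a discrete trait

The trait (4 body-size categories by default: small < 1 kg, medium
1–10 kg, large 10–100 kg, very large 100–1000 kg) evolves by a
continuous-time Markov chain with rate matrix Q per regime.  The four
standard candidates cross {single, multi} regime with {equal rates, all
rates different}: k = 1, n(n−1), 2, 2n(n−1) free parameters
respectively.  A regime painting maps each branch to a regime; a branch
paints with a clade iff all its descendant tips belong to it (stem
included), and branches ancestral to both groups take a configurable
background group.  Likelihoods use the pruning algorithm with uniform
root frequencies throughout (likelihood, fitting, ancestral states);
AIC = 2k − 2 ln L and Akaike weights w ∝ exp(−ΔAIC/2).

**Numerics.**  Transition matrices exp(Q·t) are computed by
eigendecomposition batched over branch durations, with a `scipy` `expm`
fallback whenever the eigenvector matrix is ill-conditioned or row sums
drift beyond 1e−8; the pruning pass is level-scheduled (all nodes of
equal height in one batched update) with running rescaling against
underflow.  Optimization is multi-start L-BFGS-B on log rates, bounds
[1e−8, 1e3] per Myr, because all-rates-different surfaces are multimodal;
`fit_candidate_models` warm-starts each model from its simpler neighbour
(ER seeds ARD; single-regime solutions, tiled, seed multi-regime), which
both speeds fitting and improves the optima found.  A fitted rate within
two decades of a bound sets the `at_bound` flag (e.g. an invariant trait
drives the ER rate to the zero boundary).

**A note on the published worked example.**  The Akaike-weight example in
the acceptance suite recomputes weights from a published four-model AIC
column for amniote body-size categories; the two all-rates-different
weights (0.98 and 0.017) reproduce exactly, while the two equal-rates
weights do not follow from the published AICs.  Recomputing AIC from the
published log-likelihoods with integer parameter counts suggests the two
all-rates-different AIC entries were transposed in the source table.
This package always defines AIC = 2k − 2 ln L and makes no attempt to
reverse-engineer the printed values.

## Synthetic data

The generator emulates the statistical structure the analyses assume, at
the scale of the motivating dataset, with ground truth stored for
scoring:

- **Tree**: a dated birth–death tree (defaults: 98 total tips, birth
  0.13/Myr, death 0.03/Myr) rooted at 320 Ma with its youngest tips at
  272 Ma; extinct lineages persist as fossil tips.  By default the root
  splits two equal-size birth–death subtrees — the two major lineages of
  a crown group — each on a stem spanning 10% of the window, so
  clade-level comparisons have two substantial sides.
- **Characters**: 366 unordered characters under equal-rates Mk.
  Constraint is operationalized as accessible-state restriction: branches
  inside a constrained clade move among k states (e.g. 2) while the
  background uses 6; small k forces homoplasy and a low saturation
  asymptote, which is exactly the behavioural definition of constraint
  the saturation analysis uses.  The per-branch expected change count
  (rate profile × duration) forms the true changes-scaled tree; an
  optional lognormal multiplier emulates branch-length estimation error.
  The base rate (0.01 expected changes per character per Myr at the
  root) and exponential decline (half-life 20 Myr) give tree-scale
  change counts of a few changes per character, typical of morphological
  matrices of this size.
- **Missingness**: completely-at-random cell masking at 0.45 by default
  (fossil matrices of this kind are roughly half unscored), with a
  taxon-biased beta-distributed mode for robustness checks.
- **Body size**: two-regime all-rates-different simulation.  The
  mammal-line regime permits only increases (all larger→smaller rates
  zero, smaller→larger 0.04/Myr); the reptile-line regime is
  bidirectional and biased toward decreases (0.02 up, 0.08 down),
  matching the qualitative regime contrast the analyses are designed to
  detect and giving each lineage a handful of realized size-class
  transitions over the ~50-Myr window.

**What the generator does not emulate**: correlations among characters,
clade-structured taxon sampling, preservation/collection bias, and
non-uniform state frequencies.  Passing tests therefore show that the
pipeline recovers known structure under the model's own assumptions, not
that those assumptions hold for any particular empirical dataset.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to balance statistical
resolution against a short default run: node scans use 20 replicate
60-tip, 300-character datasets with 100 null simulations per scan
(analyses of real data should use the 1000-simulation default);
calibration uses 200,000 estimator pairs; model-selection recovery uses
three replicate 600-tip trees — at a few hundred tips the 24-parameter
multi-regime model is only sometimes separable from its 12-parameter
single-regime rival by AIC, and the recovery experiment is run at a size
where the generating model is reliably identifiable.

## Scope

Bayesian inference of topology, dates, and branch rates is consumed as
annotated tree input, not re-implemented.  Alternative saturation models,
distance metrics with inapplicable-aware corrections, hidden-rate Mk
extensions, and morphospace ordination are out of scope.
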