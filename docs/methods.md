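# Methods

## Model

CoxMGM is a pairwise Markov random field over p continuous variables x,
q discrete variables y (full indicator encoding), and r censored
variables, each a pair (t_m, δ_m) with δ_m = 1 when the event was
observed.  The pairwise potentials are β_st (continuous–continuous,
symmetric), ρ_sj (continuous–discrete, one weight per level of y_j),
φ_jk (discrete–discrete, level×level matrices), γ_sm
(continuous–censored scalars), and ψ_jm (discrete–censored level
vectors).  There is no censored–censored potential, so the model cannot
represent an edge between two censored nodes; downstream metrics carry an
SS edge class anyway so pair universes always partition.

A censored node m contributes in two ways.  Its own conditional is the
Cox partial likelihood of the linear predictor η_m = γ_m'x + ψ_m(y),
with Efron's correction whenever event times tie.  In its neighbours'
conditionals it appears through the working covariate W_m z_m of a
second-order expansion of the negative partial log-likelihood at η̂_m,
where diag(W_m) = diag(l''(η̂_m)) and z_m = η̂_m − l''(η̂_m)^{-1} l'(η̂_m).
At η̂_m = 0 the product W_m z_m equals the null-model Martingale
residuals δ_i − Λ̂(t_i); this identity is exact under the Breslow
cumulative hazard, which is why the null-model residual path uses
Breslow even though all regression fitting uses Efron.

The negative log-pseudolikelihood is the sum of node-conditional losses:
Gaussian with unit conditional variance on standardized continuous
columns, multinomial-logistic for discrete nodes, Cox for censored
nodes.  Each edge parameter is shared by its two endpoint conditionals
(the standard pseudolikelihood construction), so the gradient of a pair
parameter sums both appearances.

### Optimization

Proximal gradient descent with backtracking line search: scalar
soft-thresholding for β and γ, group soft-thresholding (ℓ2 for ρ/ψ,
Frobenius for φ).  Group penalties are not size-weighted by default (the
objective has no √group-size factor); a flag enables weighting.  β and φ
are stored as full symmetric matrices; the line-search inner product
halves their contributions so that each mirrored pair counts as one free
coordinate — without this the quadratic majorization is inconsistent
with the objective and the line search collapses.  The objective trace
is non-increasing within each expansion of the working quantities; the
expansion is refreshed (IRLS-style) at the current η̂ up to `n_outer`
times (default 3), starting from the null model.  Convergence is a
relative objective change below `tol` (1e-6 for final fits, 1e-5 inside
path and stability loops).  Divergence (non-finite objective) raises
with the trace attached.

The optimizer minimizes the *mean* per-sample loss plus penalties, so a
penalty value means the same thing at any subsample size — necessary for
stability selection, which fits on subsamples of size b ≪ n.
`negative_log_pseudolikelihood`/`penalized_objective` report the summed
form (the BIC uses it).  Edges are parameter blocks whose norm exceeds
`zero_tol = 1e-6` on standardized data.

### Penalty selection

The path is log-spaced over two decades below λ_max, the first
power-of-two multiple of 0.05 at which the fitted graph is empty
(doubling search), with K = 30 points by default.  Stability profiling
draws B = 20 subsamples of size b = min(⌊10√n⌋, ⌊0.75n⌋) without
replacement (per-subsample seeds derived from the master seed by index,
so subsample order is immaterial; subsamples that lose all events for
some censored node are redrawn, at most 10 times).  All five penalties
move together along the shared path and the per-edge-type instability
curves 2θ̂(1−θ̂) are read off it; a 5-dimensional grid would cost K⁵·B
fits for no clear gain.  Selection monotonizes each curve by a running
maximum in the direction of decreasing λ and takes the smallest λ whose
monotonized instability is ≤ 0.05 (StEPS: per edge type; StARS: pooled
over all possible edges).  If no point qualifies the largest λ is
returned with a warning.  BIC scores path fits by 2·NLL + log(n)·df with
df the number of nonzero free parameters (intercepts included, each
symmetric pair once).

## Conditional-independence testing

Censored target X, continuous Y: Wald test on Y's coefficient in
Cox(X ~ Y + S), referred to a t distribution with (events − parameters)
degrees of freedom — Cox asymptotics give a normal reference; the t is
chosen deliberately as the conservative small-sample reading.  Censored
X, discrete Y: likelihood-ratio test of adding reference-encoded Y,
χ²(L−1).  Non-censored pairs: partial-correlation t-test (both
continuous), Gaussian LRT (continuous/discrete, χ²(L−1)), multinomial
LRT (both discrete, χ²((L_X−1)(L_Y−1))).  Censored members of the
conditioning set enter as their null-model Martingale residual column,
so no rows are dropped; raw censored times are never used as covariates
(expansion bias).  When both tested variables are censored, each is
used as the Cox target once with the other entering as its residual
column, and the larger p-value is returned.  The LRT target for a
discrete pair and the regression target for a continuous pair are chosen
by canonical name order, making the dispatcher exactly symmetric in its
arguments.  Newton–Raphson with step-halving (max 50 iterations,
relative log-likelihood tolerance 1e-9) drives the Cox and multinomial
fits; the multinomial solver is in-package because constraint-based
search calls it tens of thousands of times.

## Constraint-based orientation

PC-Stable freezes adjacency sets at each depth (default max depth 3;
the benchmark graphs reach 550 nodes, so unbounded depth is not
tractable) and removes an edge as soon as some conditioning set from
either frozen neighbourhood gives p > α.  Test failures
(non-convergence, singular designs) conservatively retain the edge and
are logged: a false adjacency can be pruned later, a lost one cannot be
recovered.  All p-values are cached by (pair, conditioning set).

Colliders use the majority rule: all separating sets within the final
skeleton neighbourhoods (depths ≤ max) are collected by exhaustive
re-testing, and X—Z—Y is oriented as a collider iff Z appears in fewer
than half of them; an exact tie leaves the triple unoriented and is
logged.  Meek rules R1–R4 complete the CPDAG (R4 cannot fire without
background knowledge but is implemented for closure under it).  FCI
adds possible-D-SEP pruning after a provisional collider orientation,
re-orients from scratch, and applies Zhang's rules R1–R10 to a
fixpoint; selection-bias marks are representable but no rule introduces
them under the no-selection default.  The discriminating-path rule
resolves the collider/non-collider decision by majority vote over the
recorded separating sets of the path's endpoints.

Markov blankets: parents ∪ children ∪ co-parents of children on
DAGs/CPDAGs, with undirected or circle-marked edges counted as possible
in both roles; on PAGs, adjacencies plus spouses through a common
arrowhead child (a district-style approximation).

## Benchmark generator

ER graphs place exactly ⌊N·d/2⌋ edges uniformly over pairs and orient
them by a random topological order; SF graphs grow by preferential
attachment with m = d/2 edges per new node, oriented old → new, and are
topped up by degree-weighted sampling of non-adjacent pairs so the edge
count matches the ER count exactly.  Node types are assigned uniformly
at random in 5/11 : 5/11 : 1/11 proportions (largest-remainder
rounding).  Edge coefficients are ±Uniform[0.3, 1.0]; a discrete parent
carries its coefficient times a random permutation of the contrast
(−1, 0, 1), so every edge has a single magnitude within the configured
range.

Ancestral sampling: continuous children are parent sums plus N(0, 1)
noise (roots are exactly standard normal); discrete children (3 levels
by default) are multinomial-logistic with level scores equal to an
ordered (−1, 0, 1) contrast times the parent sum; censored children draw
T from a Weibull proportional-hazards law (baseline scale 1, shape 1.5 —
an increasing hazard typical of ageing-type clinical endpoints) with the
parent sum as linear predictor.  The censoring time is exponential with
rate calibrated by root-finding on the realized event-time sample so
the expected censored fraction equals the condition (30% light, 70%
heavy); `calibrate_censoring` solves E[1 − exp(−cT)] = target with
brentq after bound doubling, which is the deterministic limit of
Monte-Carlo bisection and lands within ±1% at n = 100,000.  A censored
node acts on its children through its standardized −log T (the latent
pre-censoring risk ranking), so censoring removes observable signal on
such edges without changing the generating law — the mechanism behind
the SC/SD recall gap between light and heavy censoring.  Every node
draws from its own seed-derived substream, so datasets are bit-identical
across runs and independent of traversal order.

What the generator does not emulate: nonlinear or non-additive effects,
informative censoring, missing data, measurement error, and the heavy
correlation structure of omics panels.  Passing recovery tests on these
benchmarks therefore demonstrates correctness of the algorithms under
the model's own assumptions, not robustness to their violation (the
nonparanormal transform in `datamodel` relaxes linearity to additive
monotone effects for real continuous data, but the generator does not
exercise it).

## Evaluation conventions

Orientation precision/recall and SHD are measured against the CPDAG of
the true DAG (v-structures plus Meek closure), since observational data
cannot distinguish Markov-equivalent orientations: an estimate is not
penalized for leaving a reversible edge undirected, is charged a false
positive for asserting any orientation the MEC does not compel
(including orienting a reversible edge), and a false negative for each
compelled edge left unoriented or mis-oriented; circle marks count as
unoriented unless both endpoints match.  SHD adds one per missing
adjacency, extra adjacency, and mark-mismatched shared adjacency, and
is normalized by the MEC's edge count.  AUPRC anchors the curve at
(0, first precision), integrates by trapezoid, and never extrapolates
past the largest achieved recall.  PR points come from the λ path for
the undirected model and from the α grid
{0.001, 0.005, 0.01, 0.05, 0.1, 0.2} for the causal model.

Harrell's concordance counts pairs whose earlier time is an observed
event and whose times differ; score ties count one half.  Horizon
truncation (pairs whose earlier time exceeds τ are dropped) supports
fixed-horizon variants; the default is no horizon.

## Problem sizes in the test suite

The suite runs the recovery study at 20 nodes, degree 4, n ∈ {100, 500,
5000}, 10 seeds, with K = 10 path points and B = 10 subsamples for
StEPS profiling, and the CI-test calibration at n = 200 with 1000 null
replicates per cell — sizes chosen so the full suite completes in
minutes while the monotone trends and 3-standard-error calibration
bands remain sharp.  The oracle-equivalence check enumerates all sparse
DAGs on ≤ 5 nodes up to node relabeling (the algorithms are proven
label-invariant by a separate permutation test), and Markov-equivalence
enumeration on 4 nodes is exhaustive (543 DAGs).

## Known limitations

* StEPS averages instability over the possible edges of a type; with
  very few pairs of some type (e.g., one censored node in a small
  graph) a single flickering edge keeps the average above the 0.05
  threshold and the selection falls back to heavy regularization for
  that type.  This is the documented conservative behaviour of
  stability selection at small pair counts, not a failure mode; fixed
  penalties are preferable on very small graphs.
* The pseudolikelihood shares each edge parameter between two
  conditionals; under strong dependence chains this induces extra
  shrinkage and can admit a weak transitive edge that node-wise
  regressions would exclude.  StEPS-selected models prune these in the
  constraint-based step.
* Exact sample-duplication additivity of the objective holds for the
  Gaussian and multinomial conditionals but not the Cox terms, whose
  risk sets couple samples.
* The t reference for censored-vs-continuous Wald tests is conservative
  at small event counts; with many events it coincides with the normal.
* Both-censored CI tests use max-p symmetrization of two directional
  tests — a design choice, since CoxMGM itself has no censored–censored
  potential.
* FCI's path-based rules (R5, R9, R10) enumerate uncovered paths and
  can be slow on dense graphs; the default pipeline (MPC-Stable) does
  not use them.
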