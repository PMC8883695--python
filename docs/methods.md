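# Methods

## Model class

All computations assume linear Gaussian *Markovian* SCMs: each observable
node equals a linear combination of its DAG parents plus an exogenous error
term; errors are mutually independent normals (no correlated errors, no
cycles, no latent confounding beyond the modeled nodes).  Two motifs are
built in, each over its own observable node set:

* **Confounder** (nodes C, X, Y): C = U_C, X = βC + U_X, Y = αX + γC + U_Y.
  The treatment–outcome effect is confounded through X ← C → Y; the true
  effects are ACE = DE = α, IE = 0, identified by the backdoor/single-door
  set {C}.
* **Collider** (nodes W, X, C, Y): C = αX + βW + U_C, Y = γC + U_Y.
  Treatment X and a second cause W collide in C; the true effects are
  ACE = IE = αγ, DE = 0, identified without adjustment (β_CX · β_YC).

Error standard deviations default to 1 everywhere, matching the simulation
design being emulated; the field is configurable for robustness
experiments but no built-in analysis changes it.

The implied covariance Σ = (I − Bᵀ)⁻¹ D (I − Bᵀ)⁻ᵀ (B the edge-coefficient
matrix, D the diagonal of error variances) is the analytic oracle used to
validate the sampler, and connects d-separation to vanishing partial
correlations: every d-separated triple has partial correlation exactly zero
in Σ (checked to 1e-10 in the tests).

## Graphs and identification

d-separation follows the standard chain/fork/collider blocking rule; paths
are simple (no repeated nodes), the usual convention.  The implementation
delegates the verdict to networkx's d-separation routine; the test suite
contains an independent brute-force oracle (enumerate all simple paths,
apply the blocking definition literally) and verifies agreement on every
DAG with up to 4 nodes exhaustively plus randomized 5-node graphs.

Single-door and backdoor adjustment sets are found by exhaustive search
over subsets of the observable nodes, smallest cardinality first,
lexicographic tie-break.  With at most 4 observables this is exact,
deterministic and instantaneous; no general ID-algorithm is attempted
(semi-Markovian graphs are out of scope).  Latent error terms are not
graph nodes, so adjustment sets can never contain them — the Markovian
assumption is structural, not enforced at query time.

## Bayesian regression and the Bayes factor

Each testable implication concerns one coefficient in a multiple linear
regression.  The regression model is conjugate Bayesian ridge:

* independent N(0, prior_sd²) priors on slopes (default prior_sd = 1,
  the "standard normal prior" convention; equivalent to ridge regression
  with penalty σ²/prior_sd²);
* flat intercept prior, implemented by mean-centering outcome and design;
* residual variance σ² set by empirical-Bayes plug-in: the OLS residual
  variance of the full model (n − p − 1 denominator).

The slope posterior is then Gaussian in closed form and

  BF01 = p(β = 0 | data) / p(β = 0)   (Savage–Dickey density ratio)

equals the marginal-likelihood ratio of the restricted to the full model
under the same priors.  The closed form replaces MCMC fitting: it is
deterministic and several orders of magnitude faster, which is what makes
10³–10⁴-replicate studies take seconds.  The tests verify the closed form
against tensor-product Gauss–Legendre quadrature of the marginal
likelihoods to a relative 1e-6, and the flat-prior limit against textbook
OLS.

Decision rule: an implication expected *nonzero* is violated when
BF01 > 1; expected *zero*, when BF01 < 1.  BF01 = 1 exactly (a
measure-zero event) never counts as a violation.  A consequence worth
knowing: for a weak true nonzero coefficient c, the probability that
BF01 > 1 *increases* with n until n ≈ 1/c², because the Occam factor
√(prior_sd/posterior_sd) grows faster than the accumulated evidence
against the null.  The false-positive risk is therefore not monotone in n
for strongly unbalanced settings (e.g. γ = 0.1) within the studied range
n ∈ [10, 100], even though it vanishes asymptotically.

Degenerate inputs: rank-deficient centered designs raise a singular-design
error; n < p + 2 raises an insufficient-data error; an exactly noise-free
fit (zero residual variance) yields a point-mass posterior and a clipped,
finite BF.  Coordinate-wise shrinkage |posterior mean| ≤ |OLS| holds for
single-regressor designs; for correlated multi-regressor designs ridge
guarantees only norm shrinkage ‖posterior mean‖ ≤ ‖OLS‖, and that is what
the tests assert.

## Adaptation rules

Violations map to DAG edits one-shot: all implications are tested on the
same dataset, the edits are applied together, and the estimands are
re-derived once.  No iterative re-testing of the modified model is
performed — the modified graph's own implications are not re-checked,
matching the single-pass analyst being modeled.

Confounder: a violated nonzero-implication deletes the corresponding arrow
(β_YX|C → X→Y, β_YC|X → C→Y, β_XC → C→X).  Collider: violated
zero-implications add arrows whose direction is fixed by assumed
domain/temporal knowledge (β_YX|C → add X→Y, β_YW|C → add W→Y, β_WX → add
W→X), violated nonzero-implications delete arrows (β_CW|{X,Y} → W→C,
β_CX|{W,Y} → X→C, β_YC|{W,X} → C→Y).  All resulting graphs are sub-/
super-graphs ordered by W < X < C < Y, hence always acyclic, and an
exhaustive check over all 64 collider patterns (and all 8 confounder
patterns) confirms every resulting ACE/DE/IE plan is identifiable by
single-door adjustment — no case must be dropped as undefined.  The
confounder's 8 patterns reduce to three symbolic estimands (β_YX|C, β_YX,
or 0, always with DE = ACE and IE = 0), kept as an explicit lookup table
that cross-validates the generic plan engine.

Edge coefficients in the final estimands are posterior means from the same
ridge machinery (not OLS), for internal consistency; the difference is
O(1/n) shrinkage.  Structurally absent components are exact zeros, so
ACE = DE + IE holds identically on every estimate.

## Monte Carlo design

A study setting fixes (motif, α, β, γ, n, replicate count, master seed,
standardize flag, prior_sd).  Replicate r uses the generator seeded by
SeedSequence(master_seed, spawn_key=(r,)), so any single replicate is
reproducible in isolation and extending the replicate count preserves the
existing replicates.  The false-positive risk is the fraction of
replicates with at least one violation; effect means average over all
replicates with defined effects (zeros included as zeros) and are reported
with Monte Carlo standard errors.

The built-in registry reproduces the published coefficient grids: 16
confounder settings (α ∈ {0.25, 0.5} × balanced β = γ ∈ {0.125, 0.25,
0.5, 1} and four unbalanced pairs) and 21 collider settings (9 balanced,
12 unbalanced).  The default sample-size grid is {10, 20, …, 100}; only
the endpoints of this range are prescribed, the step is this package's
choice.  Headline analyses use 2,000 replicates rather than 10,000 — the
Monte Carlo standard errors reported alongside each estimate (~0.004 on
the mean ACE) quantify the resulting slack.

**Raw scale, not z-scores.**  The simulated columns are analyzed on their
natural scale by default.  Re-standardizing each column to z-scores is
offered as a flag (`--standardize`) but deliberately off: with unit-variance
errors and nonzero coefficients the node variances exceed 1 (e.g.
Var(X) = 1 + β²), so "all variables are N(0,1)" cannot hold jointly with
the stated structural equations, and the magnitudes of the resulting
drifted estimates (unadjusted slope α + βγ/(1+β²)) are only reproduced on
the raw scale.  Under z-scoring every coefficient and Bayes factor changes
scale and the headline numbers move further from the reported ones.

## What the generator does and does not emulate

The synthetic data are exactly the model class the procedure assumes:
linear, Gaussian, homoscedastic, fully observed, independent rows.
Passing tests therefore demonstrate the behavior of the *testing-and-
adaptation procedure under a true model*, not robustness to nonlinearity,
non-Gaussian errors, measurement error, missingness, or latent
confounding — all of which would add violations of their own in real data.
The false-positive risks measured here are in that sense lower bounds for
practice.

## Known limitations

* Two motifs only; mediators, confounded mediators, semi-Markovian and
  cyclic models are out of scope.
* The Bayes factor is the only evidence measure; no p-value or alternative
  Bayesian tests are wired in.
* The N(0,1) slope prior is applied on the raw coefficient scale; no
  predictor-based autoscaling is attempted, so results are an approximation
  to analyses whose priors are autoscaled.
* One-shot adaptation; a sequential analyst who re-derives implications
  after each edit is not modeled (a scratch experiment showed the
  difference is small for the confounder motif).
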