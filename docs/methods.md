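# Methods

This note records the statistical model, the estimation conventions, the
numerical choices, and the limits of what the bundled simulations demonstrate.

## Model and estimands

A complete balanced SW-CRT has `I` clusters in `Q` sequences observed over `J`
periods with `K` individuals per cluster-period cell. Sequence `q` crosses from
control to treatment at the start of period `q + 1`; in the standard design
`Q = J − 1`, so every cluster is untreated in period 1 and treated in period
`J`. Outcomes follow the Gaussian linear model

    Y_ijk = treatment(i, j) + φ_j + α_i + ω_ij + ε_ijk,
    α_i ~ N(0, τ_α²),  ω_ij ~ N(0, τ_ω²),  ε_ijk ~ N(0, σ_e²),

all mutually independent. The treatment term is parameterized as a single
sustained effect θ (IT), one effect per exposure time `δ_s`, `s = 1..J−1`
(ETI), or one effect per calendar period `ξ_j` (CTI). The CTI effect of the
final period is not identifiable — once every cluster is treated, `ξ_J` and the
period effect `φ_J` load on the same column — so its column is dropped at
construction time and `ξ_J ≡ 0`. For the same reason a common shift of all
final-period cells never influences any treatment coefficient, which is why the
data generator's choice `ξ_J = 0` is innocuous.

The scalar estimands are θ, the discrete exposure time-averaged effect
`ETATE = (1/(J−1)) Σ_s δ_s`, and the calendar time-averaged effect
`CTATE = (1/(J−2)) Σ_{j=2}^{J−1} ξ_j`. Continuous-time integral versions of
these estimands exist conceptually; this package implements their discrete
unweighted-mean counterparts, which is what the indicator models estimate.

## Estimation

Under balance the cluster-period means are sufficient for the fixed effects, so
all fitting happens on the `I·J` mean vector (individual-level input is
collapsed first). The working covariance per cluster is
`Var(Ȳ) [(1−γ) I_J + γ J_J]` with `γ = τ_α²/(τ_α² + τ_ω² + σ_e²/K)`; the
overall scale cancels from the GLS point estimator, which is therefore a
function of γ alone. `γ = 0` reproduces OLS on the means exactly (the
independence working model). Row order of every matrix is fixed cluster-major,
period-minor; the weight extraction relies on it.

Feasible GLS estimates the components in two exact factors of the balanced
restricted likelihood:

1. `σ̂_e²` = pooled within-cell sample variance (within-cell contrasts depend on
   no other component);
2. `(γ̂, total variance)` by a one-dimensional REML profile over γ on the
   cluster-period means, using the closed-form inverse and log-determinant of
   the compound-symmetry blocks, optimized by bounded scalar minimization on
   `[0, 0.999]` (tolerance 1e−10, with an explicit boundary check at 0).

`τ̂_α² = γ̂ · total`, `τ̂_ω² = total − τ̂_α² − σ̂_e²/K` floored at zero with a log
notice. This matches a joint individual-level REML fit to high accuracy: on a
reference replicate, lme4's `(1|cluster) + (1|cluster:period)` REML estimates
agree with ours to ~1e−5 on every component (frozen as an oracle test).
Normal-equation solves use a Cholesky factorization with a rank-checked
pseudo-inverse fallback (relative tolerance 1e−10); singular systems report the
offending columns.

## Estimand weights

Every aggregated estimator is `c'β̂ = c'(Z'V⁻¹Z)⁻¹Z'V⁻¹ Ȳ`, a fixed linear
functional of the means. The numerical engine forms this row once per
(design, fitted kind, γ), verifies that it annihilates arbitrary period-effect
vectors (two fixed trends, zeros and `1..J`, suffice by linearity; tolerance
1e−9), and projects it onto the indicator columns of the hypothesized true
structure. Constant-effect recovery (weights summing to 1 within 1e−6) is
asserted inside the engine. Cluster-level and sequence-collapsed computations
are both available and tested equal; clusters within a sequence provably carry
identical weights.

The printed closed forms (`w1`, `w2`, and the two small-design rational
functions for the ETATE-under-calendar-truth and CTATE-under-exposure-truth
weights) are implemented independently of the engine and cross-checked to 1e−8
over `Q ∈ {2..11}` and a dense γ grid. The CTATE-under-exposure-truth
closed form lives on a *truncated* layout — a 3-sequence, 4-period trial with
its final period removed, so the last sequence is never treated inside the
window — admitted via `Design(..., truncated=True)`; it is the only
non-standard layout the package accepts. One subtlety of the standard-design
CTI fit: because period-J rows are retained (they inform `φ_J`), the weight
vector under an exposure-time truth has a small nonzero entry for `δ_{J−1}`
at γ > 0; the full vector still sums to one.

## Variance estimators

- **Model-based**: `c'(Z'V̂⁻¹Z)⁻¹c` at the estimated (or supplied) overall
  scale; intervals use normal quantiles by default, switchable to a t reference
  with `I − Q` degrees of freedom.
- **Cluster-robust**: sandwich forms with per-cluster meat blocks on the
  cluster-period-mean scale, consistent with the estimation scale. CR0 uses raw
  residuals. CR2 premultiplies each cluster's residuals by the
  symmetric-square-root-type adjustment that makes the estimator exactly
  unbiased under the working covariance: with `S_i = Φ_i − Z_i B Z_i'` the
  residual covariance block, `A_i = Φ^{1/2} T^{−1/2} Φ^{−1/2}`,
  `T = Φ^{−1/2} S_i Φ^{−1/2}`, satisfies `A_i S_i A_i' = Φ_i` exactly (a test
  verifies E[CR2] equals the true variance by simulation). CR3 uses the full
  inverse `(I − H_ii)^{−1}` of the leverage block. These follow the
  clubSandwich conventions; CR2 and CR3 intervals use Satterthwaite degrees of
  freedom computed from the working covariance of the full residual vector
  (`ν = tr(Ω)²/tr(Ω²)` for the induced quadratic form), CR0 uses `I − 1`.
  A fully leveraged cluster makes the adjustment singular and is reported by
  name.

## Simulation study

The replicate driver simulates individual-level outcomes, analyzes each
replicate with the requested (fitted kind × working correlation) arms — feasible
GLS for nested exchangeable, OLS for independence — and summarizes percent
relative bias `100 (mean − truth)/truth` (an error when the truth is 0),
precision as the reciprocal of the average estimated variance, 95% coverage,
and the empirical variance of the estimates. Per-replicate failures are logged
and more than 1% aborts the study. Randomness uses one root seed with
per-replicate `SeedSequence(seed, spawn_key=(rep,))` child streams, so runs are
bitwise reproducible and replicates order-independent.

The bundled reference conditions are `I = 18`, `J = 10`, `K = 30`,
`(τ_α², τ_ω², σ_e²) = (0.1, 1/90, 1)` — `τ_ω²` stored exactly as the fraction —
giving within-period ICC 0.1, cluster autocorrelation 0.9, and γ ≈ 0.69; a
linear trend `φ = (5, …, 14)`; and effect curves `θ = 6`,
`δ = (0, 0, 0.5, 1, 2, 4, 6, 6, 6)` (ETATE 2.83̄), and
`ξ = (6, 3, 1, 0.5, 0.1, 0, 0, 0)` (CTATE 1.325). The default replicate count
is 200, chosen so the full test suite and examples run in seconds to minutes;
1000-replicate runs are available through scenario configuration. The
200-replicate Monte-Carlo checks compare means against the weight-engine
expectations within 3 Monte-Carlo standard errors; the test seed was verified
to be a typical draw (the per-seed z-scores are calibrated: across 40 seeds the
spread of 200-replicate means matches the nominal MC standard error within 8%).

## What the generator does and does not emulate

The generator produces exactly the model above: Gaussian, balanced, complete,
cross-sectional, with a correctly specified nested exchangeable structure and a
treatment effect varying along a single time scale. Passing tests therefore
demonstrate the algebraic and sampling properties of the estimators under
those conditions. They say nothing about binary or count outcomes, informative
or unequal cluster sizes, missing data, incomplete or staircase designs,
exponential-decay or unstructured correlations, covariate adjustment, or
jointly exposure- and calendar-varying ("saturated") effects — all explicitly
out of scope.

## Known limitations and honest disagreements

- Model-based intervals for the *correctly specified* ETATE/CTATE under the
  independence working model do **not** reach nominal coverage in these
  conditions: the true sampling variance of the OLS ETATE estimator is about
  5× the iid model-based value (analytically, `u'Vu` vs `σ² u'u` for the
  estimator's weight vector `u`), giving ~0.65 coverage. CR2/CR3 restore
  nominal-to-conservative coverage there. One acceptance check asserts the more
  optimistic nominal-coverage behavior and is expected to fail; it is kept
  unweakened deliberately.
- The Satterthwaite rule is applied to CR3 as well as CR2, as a convention;
  no published small-sample dof rule is specific to CR3 here.
- FGLS γ̂ is floored at 0; no uncertainty in γ̂ propagates into the model-based
  covariance (standard practice for feasible GLS).
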