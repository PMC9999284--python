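# Methods

## Measurement model and identification

Every analysis treats an ordinal item response as a cut normal liability:
`y*_{ist} = λ_{i,t} θ_{st} + ε_{ist}`, `ε ~ N(0, ψ_{i,t})`, with response
`x = #{c : τ_{i,c,t} < y*}`. One latent factor per session; the latent
vector over sessions is multivariate normal with means α, variances φ_tt
and covariances φ_ts.

The invariance sequence is identified by fixing, in the *configural*
model, all latent means to 0, all latent variances to 1, and all unique
variances to 1, with loadings and thresholds free per session.
Constraining a parameter block across sessions then frees the structural
parameters it identifies:

| level         | constrained            | freed (t > 1)        |
|---------------|------------------------|----------------------|
| configural    | —                      | —                    |
| loadings      | λ_{i,t} = λ_i          | φ_tt                 |
| threshold     | τ_{i,c,t} = τ_{i,c}    | α_t, ψ_{i,t}         |
| unique_factor | ψ_{i,t} = 1 (all t)    | —                    |

Degrees of freedom are bookkept from an explicit scalar-parameter ledger
(free / fixed / equality-group entries) against the sample moments:
`I·T·(C−1)` standardized thresholds plus `C(I·T, 2)` polychoric
correlations. The resulting df steps between adjacent levels are
`(I−1)(T−1)`, `(T−1)(I(C−2)−1)` and `I(T−1)`. The ledger accepts
per-(item, session) category counts so that a category empty at a single
session — which removes one sample threshold and one session-specific free
threshold — is representable; such reduced designs are supported for
bookkeeping, while estimation requires category counts constant over
sessions. With T = 1 every level collapses to the configural ledger.

Adding `φ_tt = 1` for all t on top of the full-invariance model costs
T − 1 df. The same standardization achieved by reparameterization instead
of constraint (`λ′ = λ√φ_tt`, `α′ = α/√φ_tt`, Φ′ the correlation form)
leaves implied moments — and hence fit — unchanged; the package verifies
this equivalence to 1e−10.

## Estimation

**Polychorics.** Two-step ML per pair: thresholds from the margins, then
the correlation maximizing the multinomial likelihood with
bivariate-normal cell probabilities, searched on the atanh scale
(tolerance 1e−8) and clamped to |ρ| ≤ 0.999. Rectangle probabilities use
Owen's T function, which is exact and fast enough for simulation suites
with hundreds of replicates. Pairwise-complete subjects are used
throughout, with per-pair sample sizes recorded; the resulting matrix is
not guaranteed positive definite and is repaired by eigenvalue clipping at
1e−4 followed by rescaling to unit diagonal. Interior empty categories are
collapsed into their lower neighbor; empty edge categories produce ±∞
threshold sentinels.

**Model fit.** Diagonally weighted least squares: minimize
`Σ_k w_k (s_k − σ_k(θ))²` over the ledger's free parameters, where the
weights are inverse asymptotic variances of the sample moments —
thresholds by the delta method on cumulative proportions, correlations
from the pairwise observed information. Because the weights absorb the
per-pair sample sizes, the minimized discrepancy is itself the test
statistic, referred to a central chi-square on the ledger df. The moment
covariance is approximated as diagonal; under that approximation the
mean-and-variance (Satterthwaite) adjustment is algebraically the
identity, so no separate scaling is applied. The statistic is therefore
approximately, not exactly, chi-square calibrated — the package's
inferential surface (df bookkeeping, nesting monotonicity, parameter
recovery, equivalence-test behavior) does not depend on exact calibration,
and no claim of numerical identity with full-weight WLSMV software is
made.

Optimization is L-BFGS-B on transformed parameters: log ψ and log φ_tt,
atanh cross-session correlations, and (first, log-increment) threshold
blocks that keep τ strictly increasing by construction. Deterministic
start: thresholds from margins, loadings from the first principal axis of
the session-1 polychorics, unit variances, cross-session correlation 0.6.
Convergence at gradient norm 1e−6 / objective change 1e−12; a unique
variance driven below 1e−4 is flagged as a Heywood pattern.

**Fit statistics.** `RMSEA = √(max(0, (T−df)/(df(N−1))))`;
CFI against the independence baseline (zero correlations, free
thresholds); SRMR over the unique off-diagonal correlation residuals only
(threshold residuals excluded — the conventional choice for
categorical-moment models; the residual interface accepts them for
symmetry). The equivalence test uses `ncp = (N−1)·df·ε₀²` with ε₀ = 0.08
by default and N the session-1 sample size (an average-per-wave option
exists). Δχ² differences that come out negative under approximate
statistics are floored at zero with a warning.

## Davidian-curve IRT

The latent density is `h(z) = P_k(z)² φ(z)` with polynomial coefficients
`c = L⁻ᵀ u`, where L is the Cholesky factor of the standard-normal moment
matrix and u a unit vector, so ∫h = 1 for every parameter setting and
k = 0 recovers the standard normal exactly. u is stored as spherical
angles but optimized on a projective half-sphere chart
`u = (1, θ)/‖(1, θ)‖`: the spherical chart has a pole exactly at the
normal-density start, where its gradient vanishes and optimization stalls.
Since h depends on u only through P², the global sign is irrelevant and
the half-sphere loses nothing.

The measurement part is a graded response model with the *normal-ogive*
link `P(X ≥ c | z) = Φ(a z − b_c)` — the same liability-threshold link as
the rest of the package. (A logistic link was tried first; fitting it to
probit-generated data leaks link misspecification into the estimated
density as spurious skewness of ±0.2–0.5.)

Estimation is maximum marginal likelihood EM on a fixed rectangular grid
of 101 points on [−6, 6] (a warning fires if fitted mass reaches the
edges). The E-step collapses data to unique response patterns; each M-step
is a small warm-started optimization, so the marginal log-likelihood is
monotone non-decreasing (asserted per iteration in the tests).
Convergence at log-likelihood gain < 1e−6.

Identification: the density's location and scale trade off against item
parameters along a nearly flat likelihood ridge, which in unconstrained
fits drifts and destabilizes the shape estimate. The M-step therefore
pins the density to quadrature mean 0 and variance 1 (SLSQP equality
constraints, applied for k ≥ 3); items carry location and scale, the
density carries pure shape. Orders 3–7 are compared by Hannan–Quinn
(`−2·loglik + 2k·log log n`, ties toward the smaller order); reported
parameter counts use one discrimination and C−1 boundaries per item plus
k density parameters. Moments and the standardized display grid come from
quadrature; an analytic normal-moment expansion serves as the independent
oracle in the tests.

## Zero-inflation score test

With λ̂ the sample mean of endorsed-symptom counts, p̂₀ = exp(−λ̂) and n₀
observed zeros: `S = (n₀/p̂₀ − n)² / (n(1/p̂₀ − 1) − nλ̂)`, referred to
χ²(1). Counts are treated as unbounded although they cannot exceed the
item count; a warning fires when λ̂ > max/2, where truncation could bite.
Counts use complete item vectors per session. Note the statistic is *not*
monotone in a latent mean shift: under a common factor it peaks at
moderate sparsity and falls again in the near-all-zero regime; the tests
assert growth over the high-count-to-sparse descent only.

## Synthetic cohorts

The generator emulates a guided-therapy register: a unidimensional latent
trait per session with declining mean (default −1.2 session-1 SD across
the course), optionally growing variance and/or skewness; AR(1)
cross-session correlation with ρ = 0.8 (plausible for weekly repeated
measures; the off-diagonal structure of real registers is unknown and
fully configurable); liability-threshold measurement with default loadings
1.3 (standardized ≈ 0.79 at ψ = 1, typical of short symptom inventories)
and default thresholds placing ≈45% of baseline liability mass at category
0 to mimic symptom-report sparsity; and monotone dropout. Two presets
mirror the instruments' shapes: 7 items × 13 sessions with the printed
retention schedule (0.91 at session 2 declining to 0.44 at session 12 and
0.10 at follow-up, linear interpolation between printed anchors), and 20
items × 4 assessment occasions (retention 0.72/0.46/0.11).

The skewed family is a shifted, scaled log-normal moment-matched to the
target mean, variance, and skewness, so the normal and skewed families
differ only in shape. The `davidian` family samples a squared-polynomial
density through a normal copula. Dropout is schedule-based (expected
observed fraction equals the configured retention) or logistic
(subject-level dropout probability with configured odds ratios per SD of
standardized covariates; dropout sessions drawn from the schedule-implied
distribution). One seed fans out into per-stage substreams so adding a
stage never perturbs another's draws; fixed seeds reproduce every array
bit-for-bit.

What the generator does *not* emulate: intermittent (non-monotone)
missingness, informative dropout tied to the latent trajectory itself,
multidimensional traits, item-specific response styles, or measurement
non-invariance beyond the explicitly configured violation blocks. Passing
tests show the pipeline recovers truth under its own assumptions and
detects the programmed violations — not that real registry data satisfy
those assumptions.

## Problem sizes and numerical choices

Recovery checks use 7 items × 4 sessions at n = 2000 with 25 replicates;
calibration suites use 500–1000 replicates at n = 2000 per test;
latent-shape checks use n = 5000 with order selection over 3–7. These
sizes give Monte-Carlo error comfortably inside the asserted bands while
keeping the full suite desk-scale. Bootstrap confidence intervals for
latent trajectories default to B = 200 subject-level resamples (each
refits the model; examples and tests use smaller B). Degenerate inputs —
all-zero margins, single-category variables, empty sessions, non-PD
correlation inputs — raise structured errors or are excluded with
warnings, as documented per function.

## Known limitations

- The discrepancy statistic is diagonally weighted; its chi-square
  calibration is approximate and conservative claims should rest on the
  equivalence test and fit indices, as the analysis itself recommends.
- Session-varying category counts are bookkeeping-only; estimation
  requires a rectangular category layout.
- No missing-data imputation of any kind: all analyses are
  pairwise-complete or complete-case per session, matching the
  non-imputed analysis design.
- The Davidian density is fitted per session; no longitudinal
  semi-nonparametric model is attempted.
- No partial-invariance search, multi-group invariance, or
  full-weight-matrix WLS.
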