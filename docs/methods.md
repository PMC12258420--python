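# Methods

## The canonical model

All routines operate on the canonical reduction of an average-equivalence
design for m outcomes:

    theta_hat ~ N_m(theta, Sigma),    nu * Sigma_hat ~ W_m(nu, Sigma),

with `theta_hat` and `Sigma_hat` independent. `theta` is the vector of true
log-scale mean differences (test minus reference), `Sigma` the covariance of
the *estimator* `theta_hat`, and `nu` the degrees of freedom behind the
covariance estimate. Paired subject-level data with n complete rows of
within-subject log differences reduce to this triple with `theta_hat` the
column means, `Sigma_hat` the sample covariance divided by n, and
`nu = n - 1`. Crossover designs fitted with a design-specific ANOVA can carry
a different `nu`; the reduction exposes it as an override rather than
guessing. Period and sequence effects, replicated designs and missing data
are out of scope.

Equivalence is formulated against a symmetric hypercube: every `|theta_j|`
below the margin `c` (default `log 1.25 = 0.2231`, the 0.80-1.25 regulatory
ratio limits). The alternative hypothesis is equivalence; the null is its
complement.

## The multivariate TOST and its power function

The conventional multivariate TOST declares equivalence when each marginal
100(1-2*alpha)% t-interval lies inside (-c, c); equivalently when
`|theta_hat_j| <= c - t_{alpha,nu} * sigma_hat_j` for every j. Whenever a
standard error exceeds `c / t_{alpha,nu}` the test cannot declare at all,
regardless of the point estimates.

The probability of declaring equivalence is a multivariate-normal rectangle
probability with limits that are random through the estimated standard
errors. Two evaluation modes are implemented:

- **Known covariance** (`nu=None`): normal quantiles, fixed limits, one
  deterministic rectangle evaluation. Used for the fast analytic studies and
  wherever a closed-form cross-check exists.
- **Estimated covariance**: the rectangle (mean `theta`, covariance `Sigma`)
  is averaged over draws of `Sigma_hat` from the scaled Wishart law. The
  rectangle depends on a draw only through the square roots of its diagonal,
  so the sampler keeps exactly those; draws whose implied interval is empty
  contribute zero, which realises the empty-rectangle convention and the
  never-declare bound without explicit indicator bookkeeping. Sampling the
  Wishart law was chosen over deterministic integration over the
  m(m+1)/2-dimensional cone because the integrand support (positive-definite
  matrices with per-axis truncation) is awkward for cubature while the
  sampler handles it implicitly.

Rectangle probabilities for m <= 2 use a vectorised closed form of the
bivariate normal CDF built on Owen's T function (`scipy.special.owens_t`),
exact to ~1e-13 and fast enough for thousands of rectangles per power
evaluation; m >= 3 falls back to scipy's Genz quasi-Monte Carlo CDF. The two
routes are cross-checked against each other in the test-suite.

Monte Carlo defaults: 10^4 Wishart draws per kernel (standard error on a
probability below ~5e-3), absolute rectangle tolerance 1e-6. One frozen draw
set is reused for every level evaluated within a kernel instance (common
random numbers), making the power a smooth deterministic function of the
level inside any one adjustment call -- the fixed-point iteration below
relies on this.

## Test size and the least favourable configuration

The size is the supremum of the declaration probability over the null. The
probability decays as any coordinate moves away from the equivalence box, so
the supremum sits on the boundary: one coordinate pinned at +-c, the others
free in [-c, c]. Reflection symmetry restricts the search to the +c faces.
Each face is searched with a derivative-free local method: an 11-point scan
of the free coordinate followed by bounded Brent refinement for m = 2 (the
scan is necessary because under strong positive correlation the objective is
identically zero over most of the face), and Nelder-Mead from the face
centre and the all-+c corner for m >= 3. Coordinate tolerance 1e-4. Ties
across faces resolve to the smallest face index; tying faces are reported as
candidates. Per-face unimodality is an assumption, documented here and
guarded by a 41-point-per-face grid oracle in the tests.

Known structural facts reproduced by the implementation and pinned by tests:
for a diagonal known covariance the maximiser is an axis point
(c, 0, ..., 0) and the size has the closed form

    {1 - Phi(z_a) - Phi(z_a - 2c/sigma)} * {1 - 2 Phi(z_a - c/sigma)}^(m-1),

strictly decreasing in m; under heteroscedasticity the pinned coordinate is
the one with the largest variance; as the correlation of a homoscedastic
pair approaches one the maximiser migrates to the (c, c) corner; and the
size is strictly below the nominal level whenever the standard errors are
positive, so the conventional test is conservative.

## The level adjustment

The alpha-TOST runs the identical decision at the corrected level

    alpha* = argzero over gamma in [alpha, 0.5) of size(gamma) - alpha.

Because the least favourable configuration moves with the level, the solver
alternates an outer refresh of lambda with an inner damped fixed point

    a_k = a_{k-1} + alpha - p(a_{k-1}, lambda, Omega, nu, c),

started at the nominal level, which contracts exponentially when the largest
standard error is not large relative to c; the trace is returned so the
geometric decay can be inspected, and a bracketing root-finder serves as an
independent oracle in the tests. Tolerances: 1e-4 on the level for both
loops (relaxed to 1e-3 inside warm-started simulation replicates), at most
50 inner and 20 outer iterations. Iterates escaping [alpha, 0.5) mark the
adjustment as non-existent -- a reported regime, not an exception; the
decision layer then falls back to the conventional level with a warning.
With a stochastic kernel the divergence guard below alpha widens to four
Monte Carlo standard errors so that noise near a vanishing adjustment is not
mistaken for divergence, and a converged level is never reported below the
nominal one.

Under independence the adjustment exists iff the largest standard error is
below `2c / Phi^{-1}(alpha^{1/m} + 1/2)` (0.2319 for m = 4 at the regulatory
margin and level -- quoted truncated as 0.231 since it bounds a strict
inequality); under near-perfect dependence the m = 1 bound applies, and
intermediate dependence sits between the two. The bound is checked
dynamically rather than required up front.

The adjusted level is applied identically to every outcome's interval --
the adjustment is one number, not a per-outcome vector -- so the alpha-TOST
intervals are never wider than the conventional ones and the method declares
whenever the conventional test does (uniform dominance; asserted on kappa
grids in the tests).

### A note on the bivariate known-covariance reference value

For the homoscedastic bivariate setting sigma = 0.1, rho = 0.8 at the
regulatory margin, this implementation yields alpha* = 0.0687 (known
covariance; 0.0702 at nu = 20, stable in nu). The value is internally
validated two ways: a bracketing root-finder on the size function returns
the same level, and a direct simulation of 4x10^5 canonical draws at the
least favourable configuration rejects at rate 0.0500 +- 0.0003 when the
test is run at this level -- i.e. the adjustment is exactly size-alpha, as
the theory requires. A published reference value (~0.079) for this setting
is reproducible only by evaluating the rectangle probability with the
*drawn* covariance in place of the true one; that variant is not the
rejection probability of the canonical model and would make the procedure
anti-conservative (true size ~0.059 at its level), so it was deliberately
not adopted.

## The simulation engine

Scenarios mirror the operating-characteristics design: theta_hat drawn
around `kappa * lambda` with kappa on a grid in [0, 1.2], each method using
its own level-dependent lambda; kappa < 1 traces power, kappa = 1 reads the
empirical size. Compound-symmetry and AR1 structures are supported. The
alpha-TOST re-adjusts from every replicate's estimated covariance: the
replicate search is warm-started from the population adjustment, restricted
to the face of the largest estimated standard error with a narrow
free-coordinate window (validated against the unrestricted search to ~2e-5
on the level), and falls back to the full scan if the windowed objective is
flat. A flag switches to a single population-level adjustment.

Desk-scale defaults are B = 2000 replicates and 2x10^3 Wishart draws per
power call, giving a binomial standard error of ~1.1 percentage points on a
rate -- enough to resolve the double-digit power gap the adjusted test shows
in the moderate-variance, high-correlation cell. The original study's
B = 5x10^4 is available by configuration. Everything is vectorised and runs
sequentially; rerunning a scenario with the same seed reproduces the curves
bit-for-bit.

### What the generator does and does not emulate

The synthetic generator draws exactly from the canonical model: normal mean
estimates, Wishart covariance estimates, independence between the two. Real
crossover data deviate from this in ways the engine deliberately ignores:
period and carry-over effects, non-normal (heavy-tailed, skewed) log
differences, outliers inflating the covariance estimate, and unbalanced or
incomplete designs. Passing the operating-characteristics tests therefore
demonstrates correctness of the procedures *under the canonical model*, not
robustness to those departures; the decision layer applied to real data
inherits whatever violations the reduction to the triple carries.

## Numerical choices and degenerate inputs

- Positive definiteness is enforced by Cholesky success; degenerate inputs
  fail loudly and are never repaired by jitter, since silent repair would
  change test sizes. Perfectly collinear outcomes must be removed upstream.
- Empty rectangles have probability exactly zero by convention.
- Near-singular correlations (|rho| within 1e-14 of 1) use the comonotone
  closed form of the bivariate CDF.
- Quantiles use the low-level `scipy.special` inverses in hot paths.
- All randomness flows through `numpy.random.Generator`; scenario seeds are
  spawned via `SeedSequence` so per-kappa and per-replicate streams are
  independent and reproducible.

## Known limitations

- No global-optimisation guarantee for the least favourable configuration
  when m > 4 or Sigma is near-singular; the grid oracle covers m = 2 and
  randomised m <= 4 checks cover the largest-variance-face property.
- The feasible adjustment (from Sigma_hat) is exactly size-alpha only in the
  population limit; at finite nu its empirical size stays at or below the
  nominal level in all simulated settings, i.e. it is slightly conservative.
- Owen's Q-function representations of univariate power are not implemented;
  a direct quadrature oracle plays that role in the tests.
- Asymmetric margins, outlier-robust variants and reference-scaled
  approaches are out of scope.
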