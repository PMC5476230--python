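# Methods

## Data-generating model

Heights follow a random-intercept / random-slope Gaussian growth model.
For child `j` at occasion `i`:

    H_ij = beta0 + u0j + (beta1 + u1j) * t_ij + e_ij
    (u0j, u1j) ~ N(0, Omega_u),   e_ij ~ iid N(0, sigma_eh^2)

with `Omega_u` parameterised by SDs `sigma_u0`, `sigma_u1` and
correlation `rho_u01`. The distal outcome is linear in the *latent*
deviations:

    BP_j = gamma0 + alpha3 * u0j + alpha4 * u1j + e_BPj,  e_BPj ~ N(0, sigma_eBP^2)

Measurement ages are drawn independently per occasion around mean ages
0, 2.5, 5, 7.5, 10 y with SD 0.5 y, except 0.025 y at birth (so ~95% of
"birth" lengths are measured within two weeks of birth). A child whose
drawn ages are not strictly increasing is redrawn wholesale — redrawing,
rather than sorting, preserves the per-occasion marginals; with 5-SD
gaps between occasions this affects roughly one child per thousand. One
age draw is shared by every replicate and scenario of a run (jitter is a
fixed design feature, not per-replicate noise); `redraw_ages` switches
to a fresh schedule per replicate.

Defaults (the fixed study conditions; units in parentheses):
`beta0 = 50` (cm), `beta1 = 9` (cm/y), `sigma_u0 = 2.5` (cm),
`sigma_u1 = 0.5` (cm/y), `rho_u01 = 0.1`, `sigma_eh = 2.0` (cm),
`gamma0 = 120` (mmHg), `alpha3 = 0.5` (mmHg/cm), `alpha4 = 2.0`
(mmHg per cm/y), `sigma_eBP = 10` (mmHg), `J = 1000` children, `I = 5`
occasions, complete data. The implied unconditional birth-length
association is `alpha1 = alpha3 + alpha4 * rho_u01 * sigma_u1/sigma_u0
= 0.54` at the defaults. One master seed spawns independent substreams
for ages, random effects, height residuals and outcome residuals, so
varying one noise source never perturbs the others.

## Estimators

**Simple two-point.** `B_hat = H_1j`, `G_hat = (H_Ij - H_1j)/(t_Ij -
t_1j)`. Both summaries carry the measurement error of their endpoint
heights, so their between-child variances exceed the latent variances
and the birth-length association is attenuated; sharing `H_1j` between
the two summaries couples them, pushing their correlation below the
latent one.

**Per-child OLS.** Intercept/slope of each child's least-squares line,
by closed-form normal equations (two parameters, five points). Sampling
noise `sigma_eh^2 (X_j'X_j)^{-1}` again inflates the variances.

**Univariate linear mixed model.** Maximum likelihood (not REML —
matching iterative generalised least squares, the fitting algorithm of
standard multilevel software, which coincides with ML for Gaussian
models). The marginal likelihood with per-child covariance
`Z_j Omega Z_j' + sigma_eh^2 I` is profiled over the fixed effects and
maximised by L-BFGS-B over a log-Cholesky parameterisation of `Omega`
plus `log sigma_eh`, with analytic gradients. Evaluations use the
Woodbury identity on 2x2 blocks, vectorised over children; a compiled
(numba) kernel mirrors the pure-numpy reference implementation, and the
two are asserted equal in the tests. Child-level predictions are BLUPs
`u_j = Omega Z_j' V_j^{-1} (y_j - X_j beta)`; estimates are
`beta_hat + u_j` ("shrunken" path).

**Re-inflation.** BLUP sample covariance understates `Omega`. The
re-inflated path applies `u* = ubar + T (u - ubar)` with
`T = L_Omega L_S^{-1}`, lower-triangular Cholesky factors of the fitted
covariance and of the sample covariance `S` (mean-centred, denominator
J; means re-added after the transform) — after which the sample
covariance equals the fitted `Omega` exactly. Lower-triangular factors
make the inflated birth-length residual a pure positive rescaling of the
shrunken one, which is what preserves its association with the outcome;
the upper-triangular orientation (reverse-order Cholesky), which mixes
the components and breaks that property, is available behind
`orientation="upper"` for the contrast experiment. The centring
convention and denominator are this package's choice; the original
software's are not documented.

**Bivariate (joint) model.** Heights and outcome are fitted
simultaneously: the stacked response per child is (5 heights, BP), the
outcome row has no occasion-level residual — its variance and its
covariances with the growth effects form the third row of a 3x3
`Omega`. The likelihood factorises as (growth marginal) x (outcome
conditional on heights), which reduces the outcome row to a scalar Schur
complement and keeps evaluations cheap. The two-stage path re-inflates
the 3-vector BLUPs simultaneously and regresses the *estimated* outcome
on the estimated summaries; algebraically this reproduces the
moment-based transform `(alpha3, alpha4) = Omega_growth^{-1}
(sigma_u0BP, sigma_u1BP)`, `alpha1 = sigma_u0BP / sigma_u0^2` exactly
(asserted in tests), which is why it is unbiased — and why its
second-stage SEs, which ignore the first-stage uncertainty, undercover.

**Cluster bootstrap.** Children are resampled with replacement; every
resample refits the full joint pipeline. A resample is implemented as a
vector of frequency weights over the original children (weighted fits
are asserted identical to expanded-data fits), warm-started from the
full-data fit, which makes ~40k refits per coverage run affordable. SE =
SD of the resample estimates; normal (±1.96 SE) and percentile
(empirical 2.5/97.5, numpy linear-interpolation quantiles) intervals are
both recorded. Resamples that fail to converge are dropped and counted;
a result with >10% failures is flagged.

**SEM.** The latent growth curve formulation estimates the structural
coefficients and their SEs directly, propagating the first-stage
uncertainty in full. With individual time scores (the default) it is an
exact reparameterisation of the joint model: same maximised likelihood,
same point estimates, honest SEs from the inverse profile-likelihood
Hessian (numerical, central differences) plus the delta method — the
profile Hessian route was checked against the full 10-parameter observed
information and agrees to six significant figures. The unconditional
model (outcome on birth length only) keeps the outcome residual free to
covary with the growth factor; the literal alternative (residual
independent of growth) is structurally misspecified under the generating
model — its pseudo-true `alpha1` is visibly biased — and is retained
only in the fixed-loadings contrast mode. Under the free-residual
reading the identity `alpha1 = alpha3 + alpha4 psi01/psi00` holds
exactly, so the refit and the plug-in transform are genuinely
interchangeable routes to the same estimate (the refit being the one
that carries a standard error).

Two contrast loadings modes exist. `birth_at_zero` anchors the birth
indicator at t=0 and is otherwise exact. `fixed_mean_ages` uses
conventional fixed time scores with a single measurement-residual
variance; under individually jittered ages the growth-rate x age-jitter
term behaves as large (~`beta1^2 * 0.25` cm^2) heteroscedastic occasion
noise that this specification cannot absorb, so it grossly distorts the
latent covariance — we document it as a cautionary contrast, not as a
usable estimator, and our reported SEM results therefore show the
default (essentially unbiased) behaviour rather than the small
attenuation sometimes reported for SEM fits of jittered-age designs,
which depends on software-specific time-score handling.

## Monte-Carlo design and metrics

Five one-at-a-time scenarios vary `sigma_u0` (1.5-3.5), `sigma_u1`
(0.2-1.0), `sigma_eh` (0.1-5), `rho_u01` (-0.6-0.6) and `sigma_eBP`
(8-12) around the defaults. Per replicate and method we record
`alpha1` (outcome on birth length) and `alpha3`, `alpha4` (outcome on
both summaries) with classical OLS SEs, or the SEM's direct estimates.
Metrics: relative bias `mean((a_hat - a)/a) * 100` with MC SE
`sd/sqrt(n)`, and coverage of `|a_hat - a| <= 1.96 SE` with binomial MC
SE. `alpha3` is recorded but never headlined (its conditional
interpretation is confounded by the reversal-paradox issue). Replicate
seeds derive from `(master_seed, scenario id, grid index, replicate)`,
so any replicate is reconstructible in isolation and results are
independent of execution order. Replicates whose fit does not converge
are dropped from that method's summary and counted (`n_converged`);
failures are rare (\<1%) at the study conditions.

Default problem sizes: 200 replicates per grid point (binomial coverage
SE ≤ 1.6 points at 95%, ~3 points mid-range), 1000 replicates for the
baseline joint-model bias (its headline claim is "<1%", so the MC error
must sit well under that), 2000 for the SEM bias at `sigma_u1 = 0.2`
(the per-replicate estimator there has ~130% relative SD), and 200x200
for the bootstrap coverage study. A `--full-scale` CLI flag raises
scenario runs to 1000 replicates.

## Numerical choices

- Optimiser: L-BFGS-B, `ftol = 1e-11` (relative), max 500 iterations;
  convergence flag taken from the optimiser. Log-Cholesky diagonals
  bounded in `[log 1e-8, 15]` and `log sigma_eh >= log 1e-4`, so
  boundary (near-singular) solutions remain finite; noiseless data push
  `sigma_eh` to its floor rather than failing.
- Starting values: method-of-moments from the per-child OLS summaries
  (their covariance minus the average OLS sampling covariance, projected
  to PD by eigenvalue clipping). Bootstrap refits warm-start from the
  full-data fit.
- BLUPs with an exactly zero fitted `Omega` return exactly zero
  residuals (the full-shrinkage limit) instead of inverting a singular
  matrix.
- Re-inflation requires a non-singular residual sample covariance;
  calibration against it is exact to ~1e-12 relative, by construction.
- Second-stage regressions solve the normal equations directly and
  reject designs with condition number above 1e12; SEs are classical,
  `dof = n - p` (frequency-weighted `n` under bootstrap weights).
- The 1.96 multiplier is used verbatim for all Wald-type intervals (not
  a t quantile), matching the coverage rule being studied.

## What the generator does and does not emulate

It reproduces the stated cohort design: complete five-occasion
trajectories, Gaussian random effects and residuals, linear growth, a
single continuous outcome, jittered but fixed measurement ages. It does
not emulate missing data or dropout, non-linear growth, non-Gaussian or
serially correlated residuals, interactions between birth size and
growth, or binary outcomes. Passing results therefore demonstrate the
estimators' behaviour under a correctly specified linear Gaussian world
— the regime in which the bias/coverage comparison is interpretable —
and say nothing about robustness to those violations.

## Known limitations

- No REML option; variance estimates carry the usual O(1/J) ML bias
  (irrelevant at J=1000).
- No standard errors for the raw moment-based transform of the joint
  covariance (the bootstrap or the SEM are the SE-bearing routes).
- The bivariate fitter assumes one outcome per child and a 2-dimensional
  growth model; crossed or three-level designs are out of scope.
- Bootstrap intervals are normal/percentile only (no BCa/studentised).
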