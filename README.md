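# simgrowth

Two-stage and joint-model estimators of the association between growth
trajectories and a later-life outcome, with a Monte-Carlo engine for
comparing their bias and confidence-interval coverage.

## The problem

Life-course epidemiology routinely asks how the *level* and *rate of
change* of an exposure relate to a distal outcome — here, how birth
length and childhood linear growth rate relate to adult systolic blood
pressure. Each child contributes a handful of noisy height measurements
`H_ij` at ages `t_ij`, plus one outcome `BP_j`. The latent quantities of
interest are each child's true birth length `B_j` and growth rate `G_j`:

    H_ij = beta0 + u0j + (beta1 + u1j) t_ij + e_ij,   (u0j, u1j) ~ N(0, Omega_u)
    BP_j = gamma0 + alpha3 u0j + alpha4 u1j + e_BPj

The targets are the conditional growth-rate association `alpha4` and the
unconditional (total) birth-length association
`alpha1 = alpha3 + alpha4 rho_u01 sigma_u1 / sigma_u0`.

Because `B_j` and `G_j` are never observed, analysts substitute
estimates, and the choice of first-stage estimator matters: measurement
error attenuates some associations, BLUP shrinkage inflates others, and
plugging estimates into a second regression understates every standard
error. This package implements the competing estimators and quantifies
exactly how much each of these failure modes costs, for statisticians
and epidemiologists choosing an analysis strategy for cohort data.

## Methods implemented

| label | first stage | second stage |
|---|---|---|
| `simple` | first height; (last − first)/elapsed time | OLS of outcome on summaries |
| `ols` | per-child least-squares line | as above |
| `mlm_shrunken` | random-intercept/slope ML fit, BLUP residuals | as above |
| `mlm_inflated` | as above + Cholesky re-inflation to the fitted covariance | as above |
| `bvm_inflated` | joint (bivariate) ML fit of heights and outcome, simultaneous re-inflation of the 3-vector residuals | OLS on the *estimated* outcome |
| `sem` | latent growth curve SEM: structural coefficients and SEs estimated directly | — |

A non-parametric cluster bootstrap (resampling children, refitting the
entire joint pipeline per resample) supplies honest standard errors for
the joint-model path.

## Worked example

```python
from simgrowth import *

schedule = draw_age_schedule(n_individuals=1000, seed=1)
data = simulate_trajectories(schedule, GrowthParams(), OutcomeParams(), seed=2)

fit = fit_univariate_lmm(data)
shrunk = blup_residuals(fit, data)
for res in (shrunk, inflate_residuals(shrunk, fit.omega)):
    est = estimates_from_residuals(fit, res)
    assoc = second_stage(est, data.outcome)
    ...

fit3, est3, assoc3 = joint_two_stage(data)
cond, uncond = fit_sem_conditional(data), fit_sem_unconditional(data)
```

prints, for one simulated cohort (reproducible from the two seeds):

```
mlm_shrunken  alpha1= 0.724 (SE 0.159)  alpha4= 1.700 (SE 0.704)
mlm_inflated  alpha1= 0.619 (SE 0.136)  alpha4= 1.498 (SE 0.620)
bvm_inflated  alpha1= 0.638 (SE 0.136)  alpha4= 1.699 (SE 0.619)
sem           alpha1= 0.638 (SE 0.164)  alpha4= 1.699 (SE 0.703)
truth         alpha1= 0.540              alpha4= 2.000
```

One draw illustrates the systematic story (which the Monte-Carlo engine
makes precise): shrunken residuals overshoot `alpha1`; univariate
re-inflation pulls `alpha4` toward the null; the joint model and the SEM
agree exactly on the point estimates (they are reparameterisations of
the same likelihood) but the SEM's SEs are honest while the two-stage
SEs are too small.

Scenario sweeps run through the engine or the CLI:

```
simgrowth run --scenario sigma_u1 --methods mlm_inflated,sem --reps 200 \
              --seed 1 --out results/
simgrowth bootstrap-coverage --reps 200 --boot 200 --seed 1 --out results/
simgrowth simulate --seed 1 --out cohort.csv
```

Each scenario varies one generating parameter over its grid (birth-length
SD, growth-rate SD, their correlation, height measurement error, outcome
noise) and reports relative bias (%) and 95%-interval coverage (%) per
method and parameter, with Monte-Carlo standard errors.

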