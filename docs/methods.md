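# Methods

## Model structure

The package implements the two reduced GUTS variants for survival under
chemical exposure. Both share the toxicokinetic (TK) stage

    dD_w/dt = k_d (C_w(t) − D_w(t)),   D_w(0) = 0,

where `C_w(t)` is the external concentration forcing [conc], `D_w(t)`
the scaled internal damage [conc] and `k_d` [1/d] the dominant rate
constant of the slowest compensating process. Because no internal
concentrations are measured, `D_w` is a latent variable on the scale of
the external concentration; for constant exposure it reduces to
`D_w(t) = C_w(1 − e^(−k_d t))`.

The toxicodynamic (TD) stage differs:

* **SD (stochastic death)** — common threshold `z` [conc], hazard
  `h(t) = b_w max(D_w(t) − z, 0) + h_b`, killing rate `b_w`
  [1/(conc·d)], background hazard `h_b` [1/d];
  `S(t) = exp(−∫₀ᵗ h(τ)dτ)`. The hazard uses the *instantaneous*
  exceedance `max(D_w(t) − z, 0)`: notation elsewhere sometimes places a
  running maximum inside the hazard, but with the instantaneous form the
  survival function is still non-increasing (the integral accumulates),
  it is the standard reduced-SD definition, and for constant exposure —
  where damage is monotone — the two coincide.

* **IT (individual tolerance)** — thresholds log-logistic across
  individuals with median `m_w` [conc] and shape `β` [-]; death is
  immediate at the first exceedance of the individual threshold, so
  `S(t) = e^(−h_b t) (1 − F(max_{0<τ≤t} D_w(τ)))` with
  `F(x) = 1/(1 + (x/m_w)^(−β))`, evaluated as `expit(β ln(x/m_w))` for
  numerical stability at extreme shapes.

### Piecewise-analytic propagation

Exposure profiles are stored as knot series with one of two
interpolation rules: piecewise-linear (default for measured chemistry —
the least surprising choice when the true interpolation is unknown; both
rules are exposed) and left-constant steps (exact for designed
rectangular pulses). On every segment the forcing is linear,
`C(τ) = c₀ + s·u`, and the TK ODE has the closed form

    D(u) = c₀ + s·u − s/k_d + (D₀ − c₀ + s/k_d) e^(−k_d u),

propagated segment by segment. The SD hazard integral
`H(t) = ∫ max(D − z, 0)` is likewise assembled per segment from the
antiderivative of `A e^(−k_d u) + B + s u`; threshold crossings are
found in closed form on constant-forcing segments and by bracketed
Brent root-solve (xtol 1e-14, i.e. well below the stated 1e-10-day
requirement) on the at-most-two monotone pieces of a linear-forcing
segment. This removes ODE-solver tolerances from the likelihood
entirely; a generic Runge-Kutta integrator survives only as a test
oracle. Beyond the last knot the profile holds its last value, so
predictions may extend past the exposure record. The damage peak
`max_{τ≤t} D_w(τ)` used by the IT model and by `MF` is computed from the
per-segment extremum (each segment's damage is unimodal).

TK linearity — damage under a scaled profile equals the scaled damage —
holds to machine precision by construction and is the basis of the
single-TK-solve `MF` computations.

## Likelihood

Survivor counts enter through the conditional-binomial model

    N(t_i) | N(t_{i−1}) ~ Binomial(N(t_{i−1}), S(t_i)/S(t_{i−1})),

summed over observation intervals and profiles. This is the standard
GUTS calibration likelihood; the count data alone determine it given
`S`. Survival values are floored at 1e-300 before logs; conditional
ratios are clamped to [0, 1] (a ratio above 1 can only be numerical and
is logged). Data that are impossible under a parameter set (deaths while
the conditional survival probability is exactly 1) yield −inf.

## Priors and sampling

Parameters are sampled on the log10 scale with log10-uniform priors.
Default bounds are design-informed:

| parameter | lower | upper | rationale |
|---|---|---|---|
| `k_d` | −ln(1−0.001)/T | −ln(0.001)/δ | 0.1% of equilibrium reachable within the experiment duration T; 99.9% within the shortest observation gap δ |
| `z`, `m_w` | min positive tested conc | max tested conc | threshold outside the tested range is unidentifiable |
| `b_w` | 1e-4 | 1e4 | weakly informative span |
| `β` | 1e-2 | 1e2 | weakly informative span |
| `h_b` | 1e-5 | −ln(0.05)/T | upper bound = rate at which only 5% of controls survive the experiment |

Sampling uses emcee's affine-invariant ensemble, one independently
seeded ensemble per chain (default 3 chains × 16 walkers, 4000/5000
warmup and 2000/5000 kept draws per chain depending on the entry point;
the pooled sample is thinned per chain to at most 10 000 draws).
Differential-evolution moves (80% DE, 20% snooker) replace the default
stretch move: the SD posterior has a curved `k_d`–`b_w` ridge on which
stretch moves strand walkers in the tails. Walkers start from the best
4 of 256 prior draws (by log-posterior), tiled and jittered. A single
user seed derives per-chain seeds through `numpy.random.SeedSequence`,
so identical seeds and settings reproduce draws bit for bit. Split
R-hat and bulk ESS (arviz) are attached per parameter; R-hat > 1.05 or
ESS < 100 appends an explicit warning to the posterior diagnostics.

Posterior quantiles use linear interpolation of order statistics
(numpy's default, type 7), so summaries are bit-reproducible.

## Endpoints

`LC(x,t)` is defined by `S(LC, t) = S(0, t)(1 − x/100)` and computed
only for constant exposure. IT has the closed form
`m_w/(1 − e^(−k_d t)) · (x/(100−x))^(1/β)`; SD requires a bracketed
root-solve above `z` (geometric bracket expansion, relative tolerance
1e-10, configurable concentration ceiling 1e9). Incipient limits are `z`
(SD, any x) and `m_w (x/(100−x))^(1/β)` (IT). Convergence of the SD
curve to `z` is slow — the gap decays like `−ln(1−x/100)/(b_w t)` — so
limit checks evaluate at horizons of thousands of days.

`MF(x,t)` multiplies the whole profile. Two baseline conventions exist
for "x% reduction": relative to survival under the unmultiplied profile,
or relative to the control. The closed-form IT expression

    MF^β = (100 + x·(maxD/m_w)^(−β)) / (100 − x)

corresponds to the profile baseline (background mortality cancels in
both conventions), so that is the default; `baseline="control"` gives
the alternative. SD solves `S(MF·C_w, t) = S(C_w, t)(1 − x/100)` by
root-solve, using TK linearity so each trial MF costs a single
exceedance integral with threshold `z/MF`.

`DRT_x`, the time after a pulse for the scaled damage to decline by x%,
is `−ln(1 − x/100)/k_d`. An alternative literal reading, `−log(x%)/k_d`,
coincides with this only at x = 50; the implementation follows the
verbal "x% reduction" definition.

Extreme effect levels are guarded: x is clipped to [0.1, 99.9] with a
warning, since endpoint uncertainty explodes toward 0 and 100%.
Posterior propagation evaluates the endpoint at every joint draw; draws
where the endpoint is undefined (e.g. no-effect draws for MF at early
times) are dropped and counted, never imputed, and more than 50%
undefined draws at a grid point is an error.

## Goodness of fit

All four measures treat one count transition as the observation unit and
condition one step ahead on the previous *observed* count (the
alternative — conditioning on simulated trajectories — changes the
numbers; the observed-count convention matches the posterior-predictive
check machinery).

* **NRMSE** — per posterior draw, one predictive count is sampled per
  observation (fixed sub-seed 777 for reproducibility); the per-draw
  RMSE is normalised by the mean observed count and summarised by the
  median and 95% CI over draws. Sampled rather than expected counts are
  used so that NRMSE and the PPC rest on the same predictive
  distribution.
* **%PPC** — percentage of observations inside their central 95%
  posterior-predictive interval, computed from the exact draw-mixture of
  binomial pmfs (no predictive sampling noise). On discrete counts with
  n ≤ 20 individuals, exact 95% intervals are conservative, so
  well-specified fits typically score in the high 90s rather than at the
  nominal 95.
* **WAIC** — deviance scale, `−2(lppd − p_waic)` with `p_waic` the
  summed posterior variance of pointwise log predictive density.
* **LOO-CV** — PSIS leave-one-transition-out elpd on the deviance
  scale, with Pareto-smoothed importance weights; the fraction of
  observations with Pareto k > 0.7 is reported and >10% triggers a
  warning. A single-draw posterior degenerates both criteria to
  −2·log-likelihood exactly.

Validation (calibrate on design A, score on design B) is a pure data
swap: all measures accept any posterior/dataset pair.

## Synthetic data generator

The generator reproduces the two published design families: constant
designs (8 constant profiles × 5 observation times over 4 days, 20
individuals per profile — 40 records) and variable designs (2–4
double-pulse profiles over 10–22 days with uneven per-profile grids of
8–35 points and 70–80 individuals, matching the per-compound record
counts 51/61/58/70/74). Since the tested concentrations are not
published, the constant ladder is a control plus 7 geometric steps
spanning [thr/4, 4·thr] of the generating threshold, which brackets the
threshold and yields informative recovery data. Variable profiles use
two one-day pulses with a 2-day (short) or 7-day (long) interval;
uneven grids are built deterministically by seeding mandatory points
around the pulses and greedily filling quarter-day candidates. Counts
are drawn by the conditional-binomial forward model with per-profile
RNG streams spawned from one seed.

What the generator does *not* emulate: measurement error on
concentrations, individual covariates, inter-replicate heterogeneity
beyond binomial noise, or time-varying background mortality. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the assumed model, not robustness to the
misspecification present in real bioassays.

## Problem sizes and numerical choices

The test suite and the acceptance script use reduced MCMC settings
(3 chains × 16 walkers, 4000 warmup / 2000 kept draws per chain) chosen
so that R-hat ≤ ~1.03 and ESS ≳ 2000 on the standard constant design;
the recovery experiment runs 20 replicates per model. Oracle comparisons
use 100 random pulse profiles (TK) and 100 random parameter draws
(endpoints). Root-solves use Brent's method with xtol 1e-12–1e-14;
quadrature appears only in test oracles.

## Known limitations

* Background hazard under IT is structurally confounded with the lower
  tail of the tolerance distribution: deaths in weakly exposed cohorts
  can be absorbed by either `h_b` or a small-`β` tail, so the `h_b`
  marginal is biased low in short experiments and its credible intervals
  under-cover relative to the nominal 95% in repeated sampling. SD does
  not share this confounding. Fixing `h_b` from dedicated control data
  is the usual remedy and is possible by setting a narrow prior.
* `LC(x,t)` is defined only under constant exposure; request it for a
  variable profile and you will get the constant-exposure answer for the
  wrong question — use `MF(x,t)` instead.
* The SD `k_d`–`b_w` ridge means point estimates of either parameter
  alone can be far from truth on 4-day constant designs even when the
  joint fit and all endpoint predictions are accurate; variable-exposure
  designs with uncorrelated pulses identify `k_d` much better.
* Exposure profiles are taken as exact; degradation or fate modelling of
  the compound between measurements is out of scope.
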