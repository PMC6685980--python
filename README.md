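# gutspy

Reduced GUTS (General Unified Threshold model of Survival)
toxicokinetic-toxicodynamic modelling for ecotoxicology, with Bayesian
calibration and full uncertainty propagation to the regulatory toxicity
endpoints `LC(x,t)`, `MF(x,t)` (a.k.a. `LPx`) and the depuration time
`DRT_x`, under both constant and time-variable (pulsed) exposure
profiles.

The package is aimed at ecotoxicologists and environmental risk
assessors who calibrate survival models on standard toxicity-test data
(survivor counts over time under controlled exposure) and need toxicity
endpoints *with credible intervals* rather than point values.

## The model

Exposure to a chemical at external concentration `C_w(t)` drives a
scaled internal damage `D_w(t)` through one-compartment first-order
kinetics with dominant rate constant `k_d` [1/d]:

    dD_w/dt = k_d (C_w(t) − D_w(t)),    D_w(0) = 0.

Two death mechanisms are supported:

* **GUTS-RED-SD** (stochastic death): all individuals share a threshold
  `z`; the hazard rate is `h(t) = b_w·max(D_w(t) − z, 0) + h_b` with
  killing rate `b_w` and background hazard `h_b`, and
  `S(t) = exp(−∫₀ᵗ h)`.
* **GUTS-RED-IT** (individual tolerance): thresholds are log-logistic
  across individuals (median `m_w`, shape `β`); death is immediate at
  the first exceedance, so
  `S(t) = exp(−h_b t)·(1 − F(max_{τ≤t} D_w(τ)))`.

Damage and the SD hazard integral are propagated **piecewise
analytically** (the ODE has a closed form on every constant or linear
segment of the exposure profile), so no numerical ODE solver enters the
likelihood. Calibration uses the conditional-binomial likelihood
`N(t_i) ~ Binomial(N(t_{i−1}), S(t_i)/S(t_{i−1}))` with log10-uniform,
design-informed priors, sampled with seeded affine-invariant ensembles
(emcee). Endpoints:

* `LC(x,t)` — constant concentration causing an x% survival reduction
  relative to control at time t (closed form for IT, root-solve for SD);
  incipient limits `z` (SD) and `m_w·(x/(100−x))^(1/β)` (IT).
* `MF(x,t)` — factor multiplying a whole exposure profile that causes an
  x% survival reduction at time t (closed form for IT via the damage
  maximum; root-solve for SD using the linearity of damage in the
  forcing).
* `DRT_x = −ln(1 − x/100)/k_d` — post-pulse depuration time.

Goodness of fit: NRMSE, %PPC (coverage of 95% posterior-predictive
intervals), WAIC and PSIS-LOO-CV on the deviance scale.

## Worked example

Simulate a standard 4-day acute test (8 constant concentrations
including a control, 20 individuals each, 5 observation days) from known
SD parameters, then calibrate and derive endpoints:

```python
import gutspy as g

true = g.SDParams(k_d=0.8, b_w=0.5, z=2.0, h_b=0.02)
design = g.table1_design("constant", "cypermethrin", threshold=true.z)
dataset = g.simulate_dataset(true, design, seed=42)

res = g.GUTSModel(dataset, model="SD").fit(seed=1, chains=3,
                                           warmup=4000, draws=2000)
print(res.summary().round(3))
```

```
     q0.025   q0.5  q0.975   rhat       ess
k_d   0.226  0.483   0.914  1.028  3355.702
b_w   0.420  0.804   1.790  1.012  5222.241
z     1.120  1.856   2.445  1.020  5819.520
h_b   0.017  0.030   0.050  1.009  5098.092
```

Every true parameter sits inside its 95% credible interval; the
threshold `z` is tightly identified by the concentration ladder while
`k_d`/`b_w` show the well-known toxicokinetic ridge of 4-day designs.
Endpoints propagate the whole joint posterior:

```python
res.lcx(x=50, t=4.0)
# LC50 at day 4: median 3.02, 95% CI [2.74, 3.38]  (concentration units)
res.depuration_time(x=50)
# DRT50: median 1.43 d, 95% CI [0.76, 3.07]
pulses = g.make_pulse_profile(2, 4.0, 1.0, [1.0, 5.0], 12.0)
res.mfx(pulses, x=50, t=12.0)
# margin of safety for the double-pulse profile: median MF 1.57 [1.42, 1.73]
res.gof().to_dict()
# NRMSE median 0.102, %PPC 100.0, WAIC 82.6, LOO 83.4 over 32 transitions
```

An `MF(50, 12) ≈ 1.6` means the whole exposure profile could be scaled
up ~1.6-fold before killing half the cohort by day 12 — the profile is
close to the toxic range.

The same workflow is available from the shell:

```bash
guts simulate --model SD --kind constant --seed 42 --out sim/
guts fit --data sim/survival.csv --model both --seed 1 --out fit/
guts lcx --posterior fit/posterior_SD.csv --model SD --x 10,50 --t 4 --out lc.csv
```

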