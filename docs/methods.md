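# Methods

## Model and procedure

`ptasim` implements a Monte Carlo probability-of-target-attainment (PTA)
pipeline for IV beta-lactam dosing. One simulation run proceeds as:

1. **Cohort.** A virtual cohort of `n_patients` carries renal-function
   covariates (serum creatinine, age, weight, sex). In the default
   configuration every patient sits at the typical covariates; a
   dispersed mode draws serum creatinine log-normally around a median.
2. **Individual parameters.** Typical clearance comes from the covariate
   model — a power law on serum creatinine,
   `tvCL(sCr) = tvCL_ref * (sCr_ref / sCr)^theta`, or a linear function
   of creatinine clearance, `CL = slope * CrCl + intercept` — and each
   patient's clearance is `CL_i = tvCL * exp(eta)`,
   `eta ~ N(0, omega^2)`. Volume may carry an analogous random effect;
   the intercompartmental parameters Q and Vp carry none, since the
   source model reports variability on clearance only.
3. **Profiles.** Concentration-time courses are exact closed forms of
   the linear one- or two-compartment model with zero-order infusion
   input, evaluated on a sampling grid. Proportional residual error
   (`C_obs = C (1 + eps)`, `eps ~ N(0, sigma^2)`, clamped at zero) can be
   applied to the sampled observations before PD evaluation — that
   placement is what makes a "with residual error" scenario differ from
   the noiseless one. Free concentration is `fu * C_obs`.
4. **Target evaluation.** The default PD index is fT%>MIC: the percent
   of grid points with free concentration strictly above the (possibly
   multiplied) MIC. fAUC:MIC (trapezoidal), Cmax:MIC and point-in-time
   threshold exceedance (toxicity troughs, using `>=`) are also
   available.
5. **PTA statistics.** Each of `n_reps` repetitions redraws the cohort's
   random effects; PTA_j is the percent of patients meeting the target
   in repetition j, and the mean PTA over repetitions is compared to the
   success threshold (default 90%). Scenario effects are summarised as
   the per-repetition ratio PTA_scenario,j / PTA_reference,j with its
   mean and empiric 90% CI (5th/95th percentiles, linear interpolation
   between order statistics). Repetitions with zero reference PTA are
   dropped and reported (`n_dropped`) rather than propagated as
   infinities.

### Closed forms

Everything is built from the step response to a constant infusion of
rate `R0` started at t = 0:

- one compartment: `S(t) = (R0/CL)(1 - e^{-ke t})`, `ke = CL/V`;
- two compartments: `S(t) = R0 [ A/(V alpha) (1 - e^{-alpha t}) +
  B/(V beta) (1 - e^{-beta t}) ]` with micro-constants `k10 = CL/V`,
  `k12 = Q/V`, `k21 = Q/Vp`, hybrid rates from
  `alpha + beta = k10 + k12 + k21`, `alpha beta = k10 k21`, and bolus
  coefficients `A = (alpha - k21)/(alpha - beta)`,
  `B = (k21 - beta)/(alpha - beta)`.

A finite infusion of duration Tinf is `S(t) - S(t - Tinf)`; repeated
doses superpose; steady state within a dosing interval follows from the
geometric series of each exponential tail
(`x r/(1-r)` accumulation with `r = e^{-lambda tau}` per term). A
truncated-superposition evaluator (summing past doses until the added
contribution is below 1e-9 mg/L) is kept alongside as an internal
cross-check; the test suite asserts both agree to 1e-6 mg/L, and that
both match numerical ODE integration to 0.1% relative.

The analytic fT%>MIC (`ft_above_mic_exact_1cmt`) inverts the
mono-exponential segments by logarithms to get exact crossing times; it
exists for the one-compartment model only and serves as the
continuous-time reference against which the grid estimator's
quantisation error (bounded by one grid step, `100 dt / window` percent)
is measured.

## Default parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| tvCL reference | 13.6 at sCr 0.47 | L/h, mg/dL | published cefepime population value for a haematologic-malignancy cohort |
| covariate exponent theta | 0.51 | — | uniquely calibrated so the model also reproduces the published 11.1 L/h at sCr 0.7 mg/dL |
| clearance BSV | 22.8% CV (`omega^2 = ln(1+CV^2)` = 0.0507) | — | observed population value; 50% CV is the stress-case scenario |
| V (central) | 18 | L | not part of the published scalar model; a realistic adult cefepime central volume, configurable |
| fu | 0.8 | — | the conventionally fixed cefepime plasma protein binding assumption |
| residual error SD | 0.2 (proportional) | — | magnitude unpublished; 20% proportional error is typical of sparse-sampling cefepime fits |
| 2-cmt split | V 12, Vp 6, Q 10 | L, L, L/h | same total volume as the 1-cmt default with a fast distribution phase |
| regimen | 2000 mg q8 h over 0.5 h; continuous 6000 mg/day | — | the study regimens |
| PD target | fT 60% > MIC 8 mg/L, first dose | — | breakpoint MIC for *P. aeruginosa*; 40/80% are battery variants |
| grid | dt 0.2 h over one dosing interval `[0, tau)` | h | baseline sampling scheme; 0.05 and 1.0 h are battery variants |
| cohort | 50 patients, 200 repetitions; age 49 y, 72 kg, male, sCr 0.47 | — | study scale; demographics chosen so Cockcroft-Gault gives ~200 mL/min at sCr 0.47 and ~130 mL/min at sCr 0.7 |

The exact-CV convention `omega^2 = ln(1 + CV^2)` is used rather than
`omega = CV`; at 22.8% the difference is under 1%.

## What the synthetic generator emulates — and what it does not

The virtual-cohort module stands in for the raw data of a population-PK
study: it reproduces the *stated distributional assumptions* (fixed or
log-normal covariates, log-normal clearance BSV, proportional residual
error, two-fold-dilution MIC distributions with prescribed MIC50/MIC90)
but none of the unmodelled structure of real patients — covariate
correlations (age-weight-creatinine), time-varying renal function,
inter-occasion variability, assay LLOQ censoring, or MIC measurement
error. Passing tests therefore demonstrate that the pipeline computes
the intended statistics correctly under the stated model, not that the
model describes any particular clinical population. Absolute PTA levels
depend on the central volume, which the source scalar model does not
fix; the directional scenario effects (renal function, target
stringency, protein binding, infusion mode, accumulation) are the
volume-robust outputs, and the acceptance suite checks exactly those
signs by pairing random draws across configurations at a shared seed.

For continuous infusions at steady state the engine admits a closed-form
check: a patient attains fT 100% > MIC iff
`CL_i < fu * R0 / MIC`, so PTA equals a log-normal CDF value. This is
used as a statistical-calibration oracle in the tests. The same formula
shows that the continuous-infusion arm cannot approach 100% under every
battery variant — lowering fu to 0.6 lowers the ceiling
`P(CL_i < fu R0 / MIC)` below 99% regardless of volume — so the test
suite asserts dominance of the continuous arm over the intermittent arm
across the whole battery, and the near-100% level at the baseline
parameterisation.

## Numerical and design choices

- **Grid convention:** half-open `[t_start, t_end)`, first point at
  `t_start`, `ceil((t_end - t_start)/dt)` points. The fT denominator is
  the number of grid points, not elapsed time — this preserves the pure
  quantisation effect of coarse sampling (an hourly grid on the worked
  example gives exactly 50% where the continuous-time value is 60.13%).
- **Evaluation windows:** one dosing interval (`[0, tau)`) for
  intermittent regimens in either phase; `[0, 24)` h for continuous
  infusions (their natural dosing interval).
- **Exceedance:** strict `>` for MIC (the index is written fT > MIC);
  `>=` for toxicity thresholds and for target success
  (attaining exactly the required fraction counts).
- **Seeding:** every stochastic element flows from
  `numpy.random.SeedSequence`. The study runner spawns one substream per
  (scenario, arm) keyed by battery position, so results are
  bit-reproducible and adding scenarios does not perturb existing ones.
  Scenario arms use independent streams (ratios pair repetitions by
  index); MIC sweeps reuse one set of draws across MICs (common random
  numbers), which makes PTA non-increasing in MIC by construction.
- **Steady-state fT window:** the paper-style "within a dosing interval"
  reading; windows spanning multiple intervals are supported by the
  grid estimator but not by the analytic crossing-time form.
- **Loading doses** are given at t = 0 with the maintenance infusion
  duration; maintenance dosing then starts one interval later.
- **Baseline phase** is the first dose, and the baseline structural
  model is one compartment; both are battery variants rather than
  baseline properties, and the resolved choice is recorded in the run
  metadata.
- **MIC distribution construction:** mass 0.3 below the MIC50,
  cumulative 0.6 at the MIC50, 0.85 just below the MIC90, 0.95 at the
  MIC90, remainder above — a deterministic layout whose empirical
  quantiles (smallest MIC at which the CDF reaches the level) equal the
  targets exactly whenever the pair is feasible on the dilution grid.

## Problem sizes

The default study is 13 scenarios x 2 arms x 200 repetitions x 50
patients x 40 grid points, evaluated as vectorised tensors; the
calibration checks use a single repetition of 10,000 patients and 100
meta-replicates of paired 200-repetition runs. These are the package's
standard operating sizes and complete in seconds.

## Known limitations

- Linear PK only: no saturable clearance, absorption phase, three or
  more compartments, or time-varying covariates.
- No dialysis/CKRT clearance models.
- The analytic fT form covers one compartment and single-interval
  windows; two-compartment fT uses the grid estimator.
- CFR is reported without a confidence interval.
- Toxicity is represented only as threshold exceedance, not as a
  toxicodynamic model.
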