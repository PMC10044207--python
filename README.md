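# ptasim

Monte Carlo **probability of target attainment (PTA)** simulation for
intravenous beta-lactam antibiotics, built around a cefepime-like
population pharmacokinetic model.

PTA analysis is the standard tool for antibiotic dose optimisation: a
validated population PK model is used to simulate thousands of virtual
patient concentration-time profiles under a candidate regimen, each
profile is scored against a pharmacodynamic (PD) target — for
beta-lactams, the percentage of the dosing interval during which the free
drug concentration exceeds the MIC (fT%>MIC) — and the PTA is the
fraction of patients meeting the target. A regimen is conventionally
judged successful when PTA exceeds 90% at the breakpoint MIC
(8 mg/L for cefepime against *Pseudomonas aeruginosa*), or when the
cumulative fraction of response (CFR), the PTA weighted across an
observed MIC distribution, exceeds 90%.

`ptasim` packages the full pipeline so that the clinical and technical
levers of a PTA analysis can be examined one at a time:

- **`ptasim.poppk`** — population model specification: typical clearance
  with a power serum-creatinine or linear creatinine-clearance covariate
  model (`tvCL(sCr) = tvCL_ref (sCr_ref / sCr)^theta`), log-normal
  between-subject variability (`omega^2 = ln(1 + CV^2)`), Cockcroft-Gault
  conversion, and individual parameter sampling.
- **`ptasim.profiles`** — exact closed-form concentration profiles for
  one- and two-compartment models under intermittent or continuous IV
  infusion: multi-dose superposition, geometric-series steady state, and
  discretisation onto a sampling grid with optional proportional
  residual error.
- **`ptasim.pdmetrics`** — fT%>MIC (grid-based and analytic continuous
  time), fAUC:MIC, Cmax:MIC, and threshold exceedance at a time point
  (e.g. neurotoxicity troughs).
- **`ptasim.pta`** — the vectorised Monte Carlo engine: per-repetition
  PTA, MIC sweeps with common random numbers, CFR, and
  scenario-vs-reference ratio statistics with empiric 90% CIs.
- **`ptasim.cohort`** — synthetic virtual cohorts, MIC distributions with
  prescribed MIC50/MIC90, and the single-factor scenario battery
  (compartments, BSV, residual error, first dose vs steady state,
  sampling interval, renal function, PD target, protein binding).
- **`ptasim.study` / `ptasim.cli`** — a configuration-driven study runner
  that executes the battery (intermittent and continuous arms), writes
  per-repetition, summary, and forest-plot comparison tables, and a
  `ptasim` command-line interface.

## Worked example

Fifty virtual patients on the baseline model (tvCL 13.6 L/h at serum
creatinine 0.47 mg/dL, 22.8% CV clearance variability, fraction unbound
0.8), dosed 2000 mg q8 h over 30 min versus a 6000 mg/day continuous
infusion, scored against fT 60% > MIC 8 mg/L after the first dose, 200
repetitions:

```python
import ptasim as pta

model = pta.default_model()
cohort = pta.generate_cohort(pta.CohortSpec(n=50))
settings = pta.SimSettings(seed=1)  # 50 patients x 200 repetitions

ii = pta.run_pta(model, cohort, pta.default_regimen(), pta.default_target(), settings)
ci = pta.run_pta(model, cohort, pta.default_continuous_regimen(), pta.default_target(), settings)
print(ii.mean_pta, ii.success)   # 5.65  False
print(ci.mean_pta, ci.success)   # 99.68 True

comp = pta.compare_scenarios(ci, ii)
print(round(comp.mean_ratio, 2), comp.ci90, comp.n_dropped)
# 23.29 (8.33, 50.0) 10
```

The intermittent regimen misses the 90% success threshold at the
breakpoint (mean PTA 5.65% under this parameterisation — cefepime's short
half-life in patients with augmented renal clearance leaves the tail of
the interval below the MIC), while the continuous infusion of the same
daily dose attains the target in essentially every patient (99.68%). The
ratio statistic says continuous dosing multiplied per-repetition PTA by
23 on average (empiric 90% CI 8.3–50); 10 of 200 repetitions had zero
reference PTA and were dropped from the ratio.

A MIC sweep with common random numbers, and the CFR against a resistant
isolate collection (MIC50 16, MIC90 512 mg/L):

```python
sweep = pta.pta_mic_sweep(model, cohort, pta.default_regimen(),
                          pta.default_target(), settings, [1, 2, 4, 8, 16])
print({m: round(r.mean_pta, 1) for m, r in sweep.items()})
# {1: 88.9, 2: 67.3, 4: 33.2, 8: 5.7, 16: 0.1}

dist = pta.generate_mic_distribution(16.0, 512.0)
full = pta.pta_mic_sweep(model, cohort, pta.default_regimen(),
                         pta.default_target(), settings, list(dist.mics))
print(round(pta.cfr(full, dist), 1))  # 19.6
```

The whole scenario battery (13 scenarios x 2 infusion arms x 200
repetitions x 50 patients) runs from the shell in about a second:

```sh
ptasim run --config examples/study_baseline.yaml --out results/ --seed 1
ptasim compare --results results/ --baseline baseline
ptasim sweep --mics 0.25..64 --reps 200
```

`results/` then holds `pta_per_rep.tsv`, `pta_summary.tsv`,
`comparisons.tsv` (forest-plot data: label, mean ratio, empiric 90% CI,
dropped repetitions) and `metadata.json` with the seed and every
resolved default.

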