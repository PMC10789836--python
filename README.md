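# mmtt-metab

Metabolic modelling and trial analysis for mixed meal tolerance test (MMTT)
studies in type 2 diabetes — built for researchers analysing randomized
dietary interventions (for example, early time-restricted carbohydrate
eating vs a Mediterranean-style control diet) with meal tests, flash
glucose monitoring and food diaries.

The package covers the full analysis chain:

* **Insulin secretion from C-peptide** — regularized non-negative
  deconvolution of the standard two-compartment C-peptide model, with
  population kinetic parameters from age, body surface area and clinical
  class, plus the exact forward model used as its oracle.
* **Beta cell function** — the two-component secretion model
  `ISR(t) = P(t)·max(0, ISR@5.5 + β-GS·(G−5.5)) + β-RS·max(0, dG/dt)`,
  fitted by penalized variable-projection least squares: glucose
  sensitivity (β-GS), ISR at 5.5 mmol/l, rate sensitivity (β-RS) and the
  potentiation factor ratio (mean P at 160–180 min over 0–20 min).
* **Metabolic indices** — HOMA-IR, Matsuda (trapezoidal whole-test form),
  fasting/total insulin clearance, fatty liver index, IFCC↔NGSP HbA1c
  conversion, Harris–Benedict energy prescriptions, macronutrient energy
  fractions.
* **CGM metrics** — duration-weighted mean, CV, time below/in/above range
  (3.9–10 mmol/l plus the 7.8 and 6.7 mmol/l thresholds), ambulatory daily
  percentile profiles.
* **Trial statistics** — exact Monte-Carlo Mann-Whitney power simulation,
  two-way repeated-measures ANOVA (diet × group, with or without the
  within-test time factor), Fisher/Mann-Whitney/Spearman with exact small-
  sample p-values, extreme-tertile stratification of after-lunch
  carbohydrate intake, dual-assessor food-diary reconciliation.
* **Synthetic cohort generator** — a fully seeded two-arm 12-week trial
  (MMTT curves forward-simulated from known beta cell parameters, 14-day
  CGM with arm-specific meal peaks, diaries, longitudinal outcomes with
  prescribed effects), so every estimator is testable against ground truth.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate one participant's meal test from known physiology, then run the
full estimation chain back over it:

```python
import numpy as np
from mmtt_metab import (population_kinetics, deconvolve_isr, fit_beta_cell,
                        homa_ir, matsuda, insulin_clearance, power_mannwhitney)
from mmtt_metab.synthetic_cohort import (SimulationConfig, simulate_mmtt,
                                         TrueSubject, mmtt_glucose_curve)

kin = population_kinetics(67, "F", 162, 78, diabetes=True)
subject = TrueSubject(
    id="demo", arm="eTRC", sex="F", age=67, weight_kg=78, height_cm=162,
    fasting_glucose=7.6,
    true_betacell=dict(glucose_sensitivity=60.0, isr_at_5_5=110.0,
                       rate_sensitivity=500.0, pot_slope=0.75),
    true_kinetics=kin, insulin_clearance_true=1.1,
)
t_fine, glucose_fine = mmtt_glucose_curve(7.6, 3.0)
profile = simulate_mmtt(subject, t_fine, glucose_fine, SimulationConfig(seed=0),
                        rng=None)  # noise-free: the chain should return the truth

isr = deconvolve_isr(profile.time_min, profile.cpeptide_pmol_l, kin, lam=1e-2)
params = fit_beta_cell(profile.time_min, profile.glucose_mmol_l, isr).params
```

Printing the results gives:

```
beta-GS      59.3 pmol min-1 (mmol/l)-1  [truth 60]
ISR@5.5     112.4 pmol/min               [truth 110]
beta-RS       488 pmol (mmol/l)-1        [truth 500]
pot. ratio   1.93                        [truth 1.96]
HOMA-IR      8.94
Matsuda      1.91
clearance    1.18 l/min                 [truth 1.10]
power       0.824 (MC SE 0.0038)
```

Reading: the deconvolution + model fit recovers the generating beta cell
parameters from the nine sampled time points (small residual deviations
come from the 1-min reconstruction grid and spline smoothing); HOMA-IR
≈ 8.9 and Matsuda ≈ 1.9 describe an insulin-resistant fasting/post-meal
state, and total insulin clearance comes back near the simulated
1.1 l/min. The last line is the trial's design computation: a two-sided
Mann-Whitney test with n = 11 per group detects a 4 mmol/mol HbA1c
difference (SD 3) with 82% power.

With measurement noise switched on (`rng=np.random.default_rng(...)`),
subject-level beta cell parameters scatter widely — the expected behaviour
of meal-model fits, which is why they are interpreted at group level.

## Command line

Every stage is also a subcommand of `mmtt-metab`:

```bash
mmtt-metab run --out runs/demo --seed 1          # full pipeline
mmtt-metab simulate --out data/ --seed 1         # cohort only
mmtt-metab deconvolve --mmtt data/mmtt.csv --subjects data/subjects.csv --out isr.csv
mmtt-metab betacell-fit --mmtt data/mmtt.csv --isr isr.csv --out betacell.csv
mmtt-metab cgm --trace data/cgm.csv --out cgm_summary.csv
mmtt-metab trial --table data/trial_table.csv --variable hba1c_mmol_mol --out out/
mmtt-metab power --n 11 --delta 4 --sd 3 --reps 10000 --seed 1
```

`run` writes a manifest (resolved config, hash, seed, versions, CONSORT
accounting) and a plain-text report; `--resume` re-executes only stages
whose outputs are missing or downstream of a change.

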