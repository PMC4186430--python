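# abpkpd

Pharmacokinetic–pharmacodynamic modelling of age-dependent amyloid-β
accumulation and γ-secretase inhibition in the Tg2576 mouse.

Tg2576 mice accumulate soluble and insoluble brain Aβ40/Aβ42 with age:
flat until ~7 months, then a steep rise to a plateau after ~20 months.
γ-secretase inhibitors (GSIs) such as MRK-560 block Aβ production — but
their apparent potency collapses as amyloid accumulates, and insoluble Aβ
only responds to weeks of dosing. This package implements an integrated
model of both phenomena for preclinical pharmacometricians: study design,
simulation, estimation and diagnostics, exercised entirely on synthetic
data.

## The model

**PK.** Two-compartment disposition with first-order absorption (closed
form, superposition over doses), saturable dose-dependent oral
bioavailability F(D) = θ₂ + (1−θ₂)/(1+(θ₁D)^θ₃), and instantaneous brain
equilibration C_br = θ₄·C_p (θ₄ = 0.31).

**Amyloid progression (AP).** A baseline-offset Hill function of age,
AP(a) = B + (α−B)·a^P/(EC_i^P + a^P), fitted per Aβ variant (soluble Aβ40:
B = 48 → α = 6640 pg/mg, a 141-fold rise; insoluble Aβ40: 29 → 39,900,
1330-fold).

**Coupled turnover with drug effect.** On an absolute-age clock,

    dA_sol/dt   = k_out,sol·AP(a)·(1 − I(C_br, A_sol)) − k_out,sol·A_sol
    dA_insol/dt = k_out,insol·(B_insol + SCALE(t)·A_sol) − k_out,insol·A_insol

with k_out,sol = 1.1 h⁻¹ (38-min half-life), k_out,insol = 0.001 h⁻¹
(~30-day half-life) and SCALE a Hill function of age in hours. Three drug
effect models are implemented: absolute (A), relative with fixed IC50 (B),
and the final model (C) in which IC50 = A_sol/SL rises with the soluble
level — from 0.11 μmol/L in 5-month-old to ~12 μmol/L in 25-month-old
animals (SL = 514, I_max = 0.86).

**Estimation & diagnostics.** Naive-pooled maximum likelihood (L-BFGS-B on
transformed parameters, profile residual variances, observed-information
SEs), OFV-based model comparison, visual predictive checks, unpaired
t-test effect summaries, and a duration-stratified regression of insoluble
on soluble reduction. A synthetic-data module generates cross-sectional
ageing data and the 23 catalogued study designs with log-normal residual
noise and optional PK between-subject variability.

See `docs/methods.md` for assumptions, parameter tables and numerical
choices.

## Worked example

One month of daily 6 μmol/kg oral dosing, simulated in a young and an old
animal under the final model:

```python
import numpy as np
from abpkpd import (PKParams, PDParams, simulate, average_soluble_reduction,
                    ic50_of_level, ap_level)
from abpkpd.datamodel import AnimalRecord, Arm, DoseEvent, Route, Strain

pk, pd = PKParams(), PDParams()
for age in (5.0, 15.0):
    animal = AnimalRecord("m1", Strain.tg2576, age, "demo", Arm.treated)
    doses = [DoseEvent(24.0 * d, 6.0, Route.oral, 1) for d in range(28)]
    res = simulate(animal, doses, pk, pd, np.linspace(0.0, 28 * 24.0, 600))
    avg = average_soluble_reduction(res, (res.times_h[0], res.times_h[-1]))
    level = ap_level(age, pd.ap)
    print(f"age {age:4.1f} mo: baseline soluble Abeta40 {level:7.1f} pg/mg, "
          f"IC50 {ic50_of_level(level, pd.sl):6.3f} umol/L, "
          f"average soluble reduction {avg:5.1f} %")
```

prints

```
age  5.0 mo: baseline soluble Abeta40    57.5 pg/mg, IC50  0.112 umol/L, average soluble reduction  82.6 %
age 15.0 mo: baseline soluble Abeta40  1346.0 pg/mg, IC50  2.619 umol/L, average soluble reduction  14.3 %
```

The same regimen that suppresses soluble Aβ40 by ~83% in a young mouse
achieves ~14% in a 15-month-old one: the accumulated soluble pool has
raised the IC50 ~23-fold, outpacing the fixed brain exposure. This is the
age-dependent efficacy loss the level-dependent-IC50 model encodes.

A thin CLI wraps the library for shell use:

```bash
abpkpd simulate --age-months 5 --daily-dose 6 --days 28 --out traj.csv
abpkpd generate --catalogue-study 8 --seed 1 --out study8.csv
abpkpd generate --xsec 300 --seed 1 --out ageing.csv
abpkpd fit ageing.csv --what ap --out fit.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch (~10 min on one
CPU): the deterministic IC50 anchors of the final model (young baseline and
25-month soluble level), the median recovered I_max and IC50 slope from
twenty simulate-and-refit replicates of a six-study synthetic world, and
the soluble/insoluble progression plateaus recovered from synthetic
cross-sectional ageing data (n = 500). All randomness derives from
`--seed`; results are written as JSON.
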