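# Methods

This note documents the models implemented in `abpkpd`, the assumptions
behind them, the numerical choices, and what the synthetic-data experiments
do and do not establish.

## Scientific setting

Tg2576 mice over-express human APP with the Swedish mutation and accumulate
amyloid-β (Aβ) in the brain with age: after a flat phase in young animals
(< 7 months), soluble and insoluble Aβ40/Aβ42 rise steeply and plateau
after ~20 months. A γ-secretase inhibitor (GSI, here MRK-560) blocks Aβ
production. The package quantifies two coupled questions: how the
age-dependent amyloid progression (AP) changes the drug's apparent potency,
and why insoluble Aβ40 responds only to treatment lasting on the order of
its own turnover half-life (~1 month).

## Pharmacokinetics

Plasma disposition is a linear two-compartment model with first-order
absorption, solved in closed form (tri-exponential per dose, superposition
over doses; i.v. boluses enter the central compartment directly). Because
doses are in μmol/kg and volumes in L/kg, concentrations are in μmol/L
without a body-weight term.

| parameter | default | units | meaning |
|---|---|---|---|
| KA (oral / s.c.) | 0.41 / 0.81 | 1/h | absorption rate constants |
| CL | 0.12 | L/h/kg | clearance |
| V2 / V3 | 0.28 / 2.9 | L/kg | central / peripheral volumes |
| Q | 7.6 | L/h/kg | inter-compartmental clearance |
| θ4 | 0.31 | – | total brain:plasma ratio |
| f_u,pl / f_u,br | 0.004 / 0.0067 | – | unbound fractions |

Oral bioavailability with the standard suspension vehicle is dose-dependent
and saturable:

    F(D) = θ2 + (1 − θ2) / (1 + (θ1·D)^θ3),   θ2 = 0.22, θ3 = 0.5,

with θ1 study-specific (reference range 0.0001–0.2; package default 0.01,
overridable per study). F → 1 as D → 0 and F → θ2 at high dose. The
cyclodextrin vehicles and the s.c. route use fixed fractions (1.0, 0.7,
0.8); i.v. is complete. The exact algebraic form of the dose-dependency
function used in the original analysis is not documented; this form
satisfies every published constraint (monotone dose-dependence, three
parameters, study-specific θ1) and is configurable.

Brain exposure assumes instantaneous equilibration of unbound drug, so
total brain concentration is θ4·C_p; unbound concentrations are obtained by
multiplying with f_u. Measured brain concentrations can be corrected for
the ~1.3% blood volume of unperfused brain tissue
(`blood_contamination_correct`).

## Amyloid progression

Drug-free Aβ levels follow a baseline-offset Hill function of age `a` in
months:

    AP(a) = B + (α − B) · a^P / (EC_i^P + a^P)

Identifying α as the plateau itself (rather than a multiplicative span)
is forced by the published fold-increase arithmetic: 6640/47 ≈ 141 and
39,900/30 = 1330. Reference parameters per variant:

| variant | α (pg/mg) | EC_i (months) | P | B (pg/mg) |
|---|---|---|---|---|
| soluble Aβ40 | 6640 | 20 | 6.4 | 48 |
| insoluble Aβ40 | 39,900 | 17 | 8.3 | 29 |
| soluble Aβ42 | 2240 | 18 | 5.9 | 34 |
| insoluble Aβ42 | 40,900 | 18 | 6.8 | 27 |

The integrated drug-effect model re-estimates the soluble-Aβ40 curve
jointly with the drug data (α 6620, EC_i 18.1, P 7.5, B 57.1); those values
are the package defaults for the coupled model.

## Integrated turnover model

Two states, both in pg/mg, on an absolute-age clock (hours since birth;
1 month = 730.5 h, which puts the insoluble-scaling inflection of 7610 h at
~10.4 months):

    dA_sol/dt   = k_out,sol · AP(a) · (1 − I) − k_out,sol · A_sol
    dA_insol/dt = k_out,insol · (B_insol + SCALE(t)·A_sol) − k_out,insol · A_insol
    SCALE(t)    = α₂ · t^P₂ / (EC_i2^P₂ + t^P₂)

Soluble production is tied to the loss rate (K_in = k_out·AP) so the
drug-free steady state equals the progression curve; this also removes the
need for a separate K_in estimate. k_out,sol is fixed at 1.1 h⁻¹
(literature brain Aβ40 half-life, 38 min); k_out,insol ≈ 0.001 h⁻¹
(half-life ~29 days) makes insoluble Aβ40 a slow low-pass filter of the
soluble signal — the mechanistic reason a 1-week treatment barely moves it.
The insoluble baseline (28.9 pg/mg) is maintained inside the production
term because the scaling term alone cannot sustain it at young ages, when
SCALE ≈ 0.

Three candidate drug-effect terms act on soluble production, driven by
total brain concentration C (an unbound-concentration toggle exists):

* **A — absolute**: production loses E_abs·C/(IC50_A + C) pg/mg/h, clamped
  at zero. Its parameters have no published values; defaults (E_abs = 60
  pg/mg/h ≈ k_out,sol × young baseline, IC50_A = 0.11 μmol/L) make the
  young-age effect near-complete, and are configurable.
* **B — relative, fixed IC50**: I = I_max·C/(IC50 + C).
* **C — relative, level-dependent IC50**: as B with IC50 = A_sol/SL.
  With SL = 514 the IC50 runs from 0.11 μmol/L at the young baseline
  (57.1/514) to ~12 μmol/L at the 25-month soluble level — the same dose
  loses efficacy as amyloid accumulates. The orientation of SL (level =
  SL × IC50) is the only one reproducing both anchors.

Final model-C values: I_max 0.86, SL 514, α₂ 6.5, EC_i2 7610 h, P₂ 9.1.
Structural cross-check: α₂ × soluble plateau = 6.5 × 6620 = 43,030, within
8% of the independently fitted insoluble plateau (39,900).

SCALE's argument is time since birth (EC_i2 carries hour units); the
alternative reading (a function of the soluble level itself) is noted but
not adopted.

## Numerics

The integrator is a fixed-step classical RK4 compiled with numba, with
segment boundaries at dose events and output times. Within a segment the
active dose set is frozen (concentrations are right-continuous at i.v.
boluses) and the forcing function is collapsed into at most four
exponential terms (λ1, λ2, and the two absorption rates), so cost is
independent of the number of doses. Step sizes: 0.05 h during/after dosing
(0.1 h inside fits), 1 h drug-free; RK4 is stable here because the fastest
rate is k_out,sol·h = 1.1·1 < 2.78. Equivalence with an adaptive LSODA
reference on the raw equations is enforced in tests at 0.5% (measured
≤ 2×10⁻⁵ for soluble, ≤ 3×10⁻⁹ for insoluble); the plasma closed form is
checked against a stiff ODE oracle at 0.1% (measured ~5×10⁻¹⁰). States are
clipped at zero after each step; initial conditions are the drug-free
steady state at birth (B, B_insol).

## Estimation

Fitting is naive-pooled maximum likelihood: terminal Aβ sampling is
destructive, so subject-level random effects are confounded with residual
error and are not estimated (between-subject PK variability exists in the
simulator only). The OFV is −2 log L. Residual models: additive,
proportional, and additive on the log scale (with the Jacobian term so
OFVs remain comparable); residual SDs are concentrated out by profile
likelihood unless fixed. Aβ residual error defaults to proportional —
the reference residual errors are reported in percent (51% soluble, 83%
insoluble), which only makes sense multiplicatively, although the original
analysis described its residual model as additive; both options are kept.

Optimisation is bounded L-BFGS-B on log-transformed (logit for I_max)
parameters. `fit_ap` uses 10 multi-starts (log-uniform within ±10× of the
data-driven initial values). `fit_pkpd` uses staged initialisation —
progression fitted to control arms first, drug parameters started neutral
(I_max 0.5, SL 100), then a joint refinement of the ten free parameters
with k_out,sol fixed at 1.1 h⁻¹ and the insoluble baseline frozen (it has
no reported uncertainty) — because full multi-start over repeated ODE fits
would not fit a desk-scale compute budget. Standard errors come from the
numerically differentiated observed information at the optimum (central
differences on the natural scale); a singular information matrix flags
them unavailable. Prediction cost is kept linear in the number of distinct
designs, not animals: animals sharing a study, start age and dosing
history share one trajectory, and all drug-free animals share a single
from-birth integration.

## Synthetic data

The generator emulates the structure the analysis assumes: cross-sectional
terminal sampling over 3.5–26 months of age, and a 23-study catalogue of
dosing designs (ages at start, arm sizes, treatment durations, dose
groups, terminal-sampling cohorts, routes, vehicles) that is available as
machine-readable fixtures. Proportional residual noise is realised as a
mean-matched log-normal, which keeps high-CV draws (83%) positive; PK
between-subject variability (V2 179%, V3 50%, brain:plasma 61% CV) is
available as log-normal factors for simulation and VPCs. Within-study
start-age ranges are sampled uniformly. Not modelled: litter/cage
structure, body weight, sex (the reference experiments used females only),
assay plate
effects — so green tests establish statistical behaviour of the estimators
under the assumed noise model, not robustness to real-world assay
artefacts.

Two estimator details in the canonical recovery recipes deserve note:

* Because the generator's "proportional" noise is exactly log-normal, the
  progression-recovery recipe (`ap_recovery`) fits the Gaussian likelihood
  on the log scale (the exact MLE) and maps concentration-scale parameters
  back to the mean scale with the log-normal factor exp(σ̂²/2). The
  proportional-Gaussian quasi-MLE targets the mean directly but with
  roughly 2.4× the sampling SD at n = 500 and CV 51%.
* The model-C recovery world is six of the 23 catalogued studies (8, 10,
  14 young; 15, 16, 17 middle/old) at their catalogued arm sizes, plus
  cross-sectional ageing data; data are generated with residual noise
  only, matching the pooled estimator's assumptions.

## Model discrimination

The three candidate drug-effect models are separated by age, not by young
data at a single regimen: under a 1-month daily 6 μmol/kg course the
models' young-age predictions nearly coincide, while middle (11-month) and
old (15-month) cohorts expose the differences (B predicts undiminished
relative effects in old animals; A predicts a fixed absolute effect that
becomes negligible relative to old-age baselines). The packaged
discrimination experiment generates model-C data from exactly this
three-age, one-regimen design and ranks A/B/C by OFV; restricted to the
young cohort, B and C are statistically indistinguishable (ΔOFV ≪ 3.84).
A caveat found while building it: with a rich young-only design (doses
spanning 0.5–70 μmol/kg plus serial washout cohorts, ~250 observations),
the level-dependent IC50 does become detectable from young data alone
(ΔOFV ≈ 12) — "similar in young animals" is a statement about that
regimen's predictions, not a universal identifiability limit.

## Diagnostics

Visual predictive checks replicate the observed design: model predictions
are computed once per design, residual noise (and per-animal PK variability
if requested) is redrawn per replicate, and 5th/50th/95th percentiles are
summarised per bin of termination age (or time). Treatment effects are
summarised as mean ± SEM per arm with an unpaired two-sided Student
t-test (Welch optional; the equal-variance variant was the era-typical
analysis-software default) at α = 0.05. The treatment-duration analysis
regresses observed insoluble reduction on the model-predicted average
soluble reduction over the treatment window, separately for 1–3-week and
4–6-week durations, with a free intercept (the intercept handling in the
original analysis is not documented).

## Known limitations

* The functional forms for bioavailability, brain exposure, progression
  and the turnover system are reconstructions — their exact algebraic
  forms in the original analysis are not documented. Every reconstruction
  is pinned by published anchor quantities (asymptotes, fold changes,
  IC50 endpoints, half-lives) and the structural cross-check above.
* Published per-animal effect sizes are not reproducible as point values:
  they depend on study-specific θ1 values that were only published as a
  range.
* No Aβ42 drug-effect dynamics (no such data existed); Aβ42 is covered by
  the progression model only.
* Between-subject variability is simulated, never estimated; OFVs are
  therefore not comparable to mixed-effects (NONMEM) objective values.
* The fixed-step integrator trades a tolerance knob for a step-size knob;
  pathological parameter regions (k_out,insol near its 1 h⁻¹ bound with
  h = 1 h drug-free steps) are stable but less accurate than the default
  regime. Fits bound k_out,insol at 1 h⁻¹.
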