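"""Synthetic dataset generator with the statistical structure the analysis
assumes: cross-sectional terminal Aβ sampling over age, multi-study dosing
designs, residual noise and (for simulation only) PK between-subject
variability.

Proportional residual noise is realised as a mean-matched log-normal so
generated concentrations stay positive even at the high CVs seen for
insoluble Aβ (83%). Every generator records its seed in the dataset
metadata and is bit-reproducible for a given seed (numpy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    AnimalRecord,
    Arm,
    Dataset,
    DEFAULT_CONVENTIONS,
    DoseEvent,
    Endpoint,
    Observation,
    Route,
    Strain,
    UnitConventions,
    ValidationError,
)
from .estimation import ErrorModel
from .pk import PKParams, pk_profile
from .pkpd import PDParams, simulate
from .progression import APParams, DEFAULT_PROGRESSION_PARAMS, ap_level

#: days per month under the package time convention (730.5 h / 24)
DAYS_PER_MONTH = DEFAULT_CONVENTIONS.hours_per_month / 24.0
WEEKS_PER_MONTH = DAYS_PER_MONTH / 7.0

AB_VARIANTS = (Endpoint.sol_ab40, Endpoint.insol_ab40,
               Endpoint.sol_ab42, Endpoint.insol_ab42)


def weeks_to_months(weeks: float) -> float:
    return weeks / WEEKS_PER_MONTH


@dataclass
class NoiseSpec:
    """Residual error per endpoint plus PK between-subject variability."""

    residual: dict = field(default_factory=dict)   # Endpoint -> ErrorModel
    pk_bsv: dict = field(default_factory=dict)     # param name -> log-normal CV
    lloq: dict = field(default_factory=dict)       # Endpoint -> threshold
    seed: int = 0

    @classmethod
    def reference(cls, seed: int = 0, with_bsv: bool = False) -> "NoiseSpec":
        """Residual CVs of the final model (51% soluble, 83% insoluble Aβ40)
        and, optionally, the reported PK BSV (V2 179%, V3 50%, ratio 61%)."""
        residual = {
            Endpoint.sol_ab40: ErrorModel("proportional", 0.51),
            Endpoint.insol_ab40: ErrorModel("proportional", 0.83),
        }
        bsv = {"v2": 1.79, "v3": 0.50, "brain_plasma_ratio": 0.61} if with_bsv else {}
        return cls(residual=residual, pk_bsv=bsv, seed=seed)


def _draw_noisy(rng: np.random.Generator, mean: float, err: ErrorModel | None) -> float:
    """One noisy, non-negative observation around a model mean."""
    if err is None or err.sd is None or err.sd == 0:
        return float(mean)
    if err.kind == "proportional":
        # mean-matched log-normal: E[x] = mean, CV = sd
        sigma = math.sqrt(math.log1p(err.sd ** 2))
        return float(mean * rng.lognormal(-0.5 * sigma ** 2, sigma))
    if err.kind == "additive_log":
        return float(mean * rng.lognormal(0.0, err.sd))
    # additive: truncated at zero by rejection
    for _ in range(1000):
        x = rng.normal(mean, err.sd)
        if x >= 0:
            return float(x)
    return 0.0


def _observe(rng, animal_id, time_h, endpoint, mean, noise: NoiseSpec) -> Observation:
    err = noise.residual.get(endpoint)
    value = _draw_noisy(rng, mean, err)
    lloq = noise.lloq.get(endpoint, math.nan)
    blq = bool(np.isfinite(lloq) and value < lloq)
    return Observation(animal_id=animal_id, time_h=time_h, endpoint=endpoint,
                       value=value, blq_flag=blq, lloq=lloq)


# ---------------------------------------------------------------------------
# cross-sectional drug-free data (terminal sampling over age)
# ---------------------------------------------------------------------------

def generate_cross_sectional(n_animals: int, age_range_months, ap,
                             noise: NoiseSpec, *,
                             ages: np.ndarray | None = None,
                             study_id: str = "xsec",
                             arm: Arm = Arm.naive) -> Dataset:
    """Drug-free terminal Aβ observations across age.

    ``ap`` is an :class:`APParams` or a list of them (one observation per
    animal per variant). Ages are uniform on ``age_range_months`` unless an
    explicit age vector is supplied.
    """
    ap_list = [ap] if isinstance(ap, APParams) else list(ap)
    if not ap_list:
        raise ValidationError("at least one APParams required")
    rng = np.random.default_rng(noise.seed)
    if ages is None:
        lo, hi = float(age_range_months[0]), float(age_range_months[1])
        if not (0 < lo < hi <= 30):
            raise ValidationError("age range must satisfy 0 < lo < hi <= 30")
        ages = rng.uniform(lo, hi, size=n_animals)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.size != n_animals:
            raise ValidationError("ages length must equal n_animals")

    animals, observations = [], []
    for i, age in enumerate(ages):
        aid = f"{study_id}-{i + 1}"
        animals.append(AnimalRecord(aid, Strain.tg2576, float(age), study_id, arm))
        for params in ap_list:
            mean = ap_level(age, params)
            observations.append(_observe(rng, aid, 0.0, params.variant, mean, noise))
    return Dataset(animals=animals, doses={}, observations=observations,
                   metadata={"seed": noise.seed, "generator": "cross_sectional",
                             "rng": "numpy PCG64"})


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------

@dataclass
class StudyDesignSpec:
    """One preclinical study arm layout: ages, dosing, terminal sampling."""

    study_id: str
    strain: Strain
    age_at_start_months: float | tuple[float, float]
    n_treated: int
    n_vehicle: int
    treatment_days: int
    daily_doses: list[float]        # μmol/kg; one treated group per dose
    route: Route = Route.oral
    vehicle: int = 1
    sample_times_post_dose_h: list[float] = field(default_factory=lambda: [3.0])
    endpoints: list[Endpoint] = field(
        default_factory=lambda: [Endpoint.sol_ab40, Endpoint.insol_ab40])
    notes: str = ""

    def __post_init__(self):
        if self.n_treated < 1:
            raise ValidationError("n_treated must be >= 1")
        if self.n_vehicle < 0:
            raise ValidationError("n_vehicle must be >= 0")
        if any(d <= 0 for d in self.daily_doses):
            raise ValidationError("doses must be > 0")
        if any(t < 0 for t in self.sample_times_post_dose_h):
            raise ValidationError("sample times must be >= 0")
        if self.treatment_days < 1:
            raise ValidationError("treatment_days must be >= 1")

    def draw_start_age(self, rng: np.random.Generator) -> float:
        a = self.age_at_start_months
        if isinstance(a, tuple):
            return float(rng.uniform(a[0], a[1]))
        return float(a)

    def dose_events(self, amount: float) -> list[DoseEvent]:
        return [DoseEvent(24.0 * day, amount, self.route, self.vehicle)
                for day in range(self.treatment_days)]

    @property
    def last_dose_h(self) -> float:
        return 24.0 * (self.treatment_days - 1)


def _split(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_study(spec: StudyDesignSpec, pk: PKParams, pd: PDParams,
                   noise: NoiseSpec, *,
                   conventions: UnitConventions = DEFAULT_CONVENTIONS) -> Dataset:
    """Simulate one study: dosing records plus noisy terminal observations.

    Treated animals are split evenly across dose groups, then across
    terminal-sampling cohorts; vehicle animals across cohorts only. Aβ40
    endpoints come from the integrated PKPD simulation; drug-concentration
    endpoints from the closed-form PK. With PK BSV, each animal gets its own
    log-normally perturbed PK parameter set.
    """
    for e in spec.endpoints:
        if Endpoint(e) not in (Endpoint.sol_ab40, Endpoint.insol_ab40,
                               Endpoint.plasma_conc, Endpoint.brain_conc_total):
            raise ValidationError(f"generate_study cannot simulate {e} under drug")
    if spec.strain is not Strain.tg2576:
        bad = [e for e in spec.endpoints if Endpoint(e) in
               (Endpoint.sol_ab40, Endpoint.insol_ab40)]
        if bad:
            raise ValidationError("Aβ endpoints require Tg2576 animals")

    rng = np.random.default_rng(noise.seed)
    has_bsv = any(v > 0 for v in noise.pk_bsv.values())
    animals, doses, observations = [], {}, []
    counter = 0
    sim_cache: dict = {}

    def _simulate_animal(animal, dose_list, pk_i, t_rel):
        key = None
        if not has_bsv:
            key = (round(animal.age_at_start_months, 9),
                   tuple((d.time_h, d.amount) for d in dose_list), round(t_rel, 6))
            if key in sim_cache:
                return sim_cache[key]
        res = simulate(animal, dose_list, pk_i, pd, np.array([t_rel]),
                       conventions=conventions)
        out = (float(res.a_sol[0]), float(res.a_insol[0]))
        if key is not None:
            sim_cache[key] = out
        return out

    ab_endpoints = [Endpoint(e) for e in spec.endpoints
                    if Endpoint(e) in (Endpoint.sol_ab40, Endpoint.insol_ab40)]
    drug_endpoints = [Endpoint(e) for e in spec.endpoints
                      if Endpoint(e) in (Endpoint.plasma_conc, Endpoint.brain_conc_total)]
    cohort_sizes_by_dose = [
        _split(n, len(spec.sample_times_post_dose_h))
        for n in _split(spec.n_treated, len(spec.daily_doses))
    ]

    def _add_animal(arm, dose_list, termination_rel):
        nonlocal counter
        counter += 1
        aid = f"{spec.study_id}-{counter}"
        age0 = spec.draw_start_age(rng)
        animal = AnimalRecord(aid, spec.strain, age0, spec.study_id, arm)
        animals.append(animal)
        if dose_list:
            doses[aid] = dose_list
        pk_i = replace(pk, bsv_omegas=noise.pk_bsv).with_bsv(rng) if has_bsv else pk
        if ab_endpoints:
            a_sol, a_insol = _simulate_animal(animal, dose_list, pk_i, termination_rel)
            means = {Endpoint.sol_ab40: a_sol, Endpoint.insol_ab40: a_insol}
            for e in ab_endpoints:
                observations.append(
                    _observe(rng, aid, termination_rel, e, means[e], noise))
        if drug_endpoints:
            start_h = conventions.age_to_hours(age0)
            shifted = [replace(d, time_h=start_h + d.time_h) for d in dose_list]
            prof = pk_profile(np.array([start_h + termination_rel]), shifted,
                              pk_i, spec.study_id)
            means = {Endpoint.plasma_conc: float(prof.plasma_conc[0]),
                     Endpoint.brain_conc_total: float(prof.brain_conc_total[0])}
            for e in drug_endpoints:
                observations.append(
                    _observe(rng, aid, termination_rel, e, means[e], noise))

    for dose_amt, cohort_sizes in zip(spec.daily_doses, cohort_sizes_by_dose):
        dose_list = spec.dose_events(dose_amt)
        for t_post, n_cohort in zip(spec.sample_times_post_dose_h, cohort_sizes):
            for _ in range(n_cohort):
                _add_animal(Arm.treated, dose_list, spec.last_dose_h + t_post)
    for t_post, n_cohort in zip(spec.sample_times_post_dose_h,
                                _split(spec.n_vehicle, len(spec.sample_times_post_dose_h))):
        for _ in range(n_cohort):
            _add_animal(Arm.vehicle, [], spec.last_dose_h + t_post)

    return Dataset(animals=animals, doses=doses, observations=observations,
                   metadata={"seed": noise.seed, "generator": "study",
                             "study_id": spec.study_id, "rng": "numpy PCG64"})


# ---------------------------------------------------------------------------
# reference multi-study design catalogue (23 in-house study layouts)
# ---------------------------------------------------------------------------

_PK_ENDPOINTS = [Endpoint.plasma_conc, Endpoint.brain_conc_total]
_SOL_ONLY = [Endpoint.sol_ab40]
_SOL_INSOL = [Endpoint.sol_ab40, Endpoint.insol_ab40]


def study_catalogue() -> list[StudyDesignSpec]:
    """Machine-readable specs of the 23 reference in-house study designs.

    Start ages are catalogued in weeks (laboratory convention) and
    converted to months here (30.4375 days/month). The two PK-only studies
    without a recorded start age use a nominal 3.0 months. Study 5
    combined oral and i.v. arms; the oral arm is kept as primary.
    """
    w = weeks_to_months
    rows = [
        ("1", Strain.c57bl6, w(10), 9, 9, 7, [30.0], Route.oral, 1,
         [4.5, 172.5], _PK_ENDPOINTS, ""),
        ("2", Strain.c57bl6, w(14), 6, 3, 4, [7.5, 30.0], Route.sc, 2,
         [3.0], _PK_ENDPOINTS, ""),
        ("3", Strain.c57bl6, w(15), 12, 6, 4, [7.5, 30.0], Route.sc, 2,
         [3.0], _PK_ENDPOINTS, ""),
        ("4", Strain.c57bl6, 3.0, 3, 0, 1, [10.0], Route.sc, 2,
         [0.5, 1.5, 3.0, 5.0, 7.0, 24.0], _PK_ENDPOINTS,
         "PK study; start age not stated, nominal 3.0 months"),
        ("5", Strain.c57bl6, 3.0, 6, 0, 1, [3.0, 10.0], Route.oral, 1,
         [0.016, 0.08, 0.36, 0.66, 1.0, 3.0, 6.0, 24.0, 48.0], _PK_ENDPOINTS,
         "PK study; oral and i.v. arms, oral kept; start age nominal"),
        ("6", Strain.littermate, w(28), 15, 10, 28, [30.0], Route.oral, 1,
         [4.5], _PK_ENDPOINTS, ""),
        ("7", Strain.tg2576, w(20), 10, 10, 4, [70.0], Route.oral, 1,
         [3.0], _SOL_ONLY, ""),
        ("8", Strain.tg2576, w(24), 30, 15, 30, [0.5, 6.0], Route.oral, 1,
         [3.0], _SOL_INSOL, ""),
        ("9", Strain.tg2576, w(24), 30, 15, 94, [0.5, 6.0], Route.oral, 1,
         [3.0], _SOL_INSOL, ""),
        ("10", Strain.tg2576, w(24), 74, 30, 29, [1.0, 3.0, 6.0], Route.oral, 1,
         [3.0], _SOL_INSOL, ""),
        ("11", Strain.tg2576, w(24), 16, 16, 30, [6.0], Route.oral, 1,
         [3.0], _SOL_INSOL, ""),
        ("12", Strain.tg2576, w(25), 6, 6, 1, [70.0], Route.oral, 1,
         [3.0], _SOL_ONLY, ""),
        ("13", Strain.tg2576, w(25), 24, 6, 4, [1.0, 3.0, 7.5], Route.oral, 1,
         [3.0], _SOL_ONLY, ""),
        ("14", Strain.tg2576, w(25), 30, 30, 1, [70.0], Route.oral, 1,
         [3.0, 6.0, 24.0, 48.0, 120.0], _SOL_ONLY, ""),
        ("15", Strain.tg2576, w(36), 20, 20, 8, [6.0], Route.oral, 3,
         [3.0], _SOL_INSOL, ""),
        ("16", Strain.tg2576, w(60), 27, 27, 4, [6.0], Route.oral, 1,
         [3.0], _SOL_ONLY, ""),
        ("17", Strain.tg2576, w(68), 11, 10, 4, [6.0], Route.oral, 1,
         [3.0], _SOL_INSOL, ""),
        ("18", Strain.tg2576, (w(81), w(89)), 80, 80, 1, [70.0], Route.oral, 1,
         [6.0, 24.0, 48.0, 96.0], _SOL_ONLY, ""),
        ("19", Strain.tg2576, w(32), 12, 12, 4, [30.0], Route.oral, 1,
         [4.5], _SOL_ONLY, "Tg2576 + littermates; Tg arm kept"),
        ("20", Strain.tg2576, w(32), 12, 8, 21, [30.0], Route.oral, 1,
         [4.5], _SOL_INSOL, "Tg2576 + littermates; Tg arm kept"),
        ("21", Strain.tg2576, w(36), 30, 30, 8, [6.0], Route.oral, 3,
         [3.0], _SOL_INSOL, "Tg2576 + littermates; Tg arm kept"),
        ("22", Strain.tg2576, (w(24), w(28)), 34, 12, 45, [30.0], Route.oral, 1,
         [4.5], _SOL_INSOL, "Tg2576 + littermates; Tg arm kept"),
        ("23", Strain.tg2576, (w(37), w(40)), 16, 16, 28, [30.0], Route.oral, 1,
         [4.5], _SOL_INSOL, "Tg2576 + littermates; Tg arm kept"),
    ]
    return [
        StudyDesignSpec(study_id=sid, strain=strain, age_at_start_months=age,
                        n_treated=nt, n_vehicle=nv, treatment_days=days,
                        daily_doses=list(dose_list), route=route, vehicle=veh,
                        sample_times_post_dose_h=list(samples),
                        endpoints=list(endpoints), notes=notes)
        for (sid, strain, age, nt, nv, days, dose_list, route, veh,
             samples, endpoints, notes) in rows
    ]
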