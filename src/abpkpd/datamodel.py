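"""Domain types, event-record dataset I/O, unit conventions and BLQ handling.

The event-record layout follows the NONMEM convention: one row per dosing
event (EVID=1) or observation (EVID=0), with DVID distinguishing endpoints
(drug concentrations in plasma/brain, soluble/insoluble brain Aβ40/Aβ42).
Aβ concentrations are in pg per mg brain tissue; drug concentrations in
μmol/L; doses in μmol/kg; times in hours since study start.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """Input table does not have the required columns."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


class Route(str, enum.Enum):
    oral = "oral"
    sc = "sc"
    iv = "iv"


#: aliases accepted on input (NONMEM-style tokens and literature abbreviations)
_ROUTE_ALIASES = {
    "oral": Route.oral, "po": Route.oral, "p.o.": Route.oral,
    "sc": Route.sc, "s.c.": Route.sc,
    "iv": Route.iv, "i.v.": Route.iv,
}


class Endpoint(str, enum.Enum):
    plasma_conc = "plasma_conc"        # μmol/L
    brain_conc_total = "brain_conc_total"  # μmol/L
    sol_ab40 = "sol_ab40"              # pg/mg
    insol_ab40 = "insol_ab40"          # pg/mg
    sol_ab42 = "sol_ab42"              # pg/mg
    insol_ab42 = "insol_ab42"          # pg/mg


#: DVID integer codes used in the event-record CSV
DVID_CODES = {
    Endpoint.plasma_conc: 1,
    Endpoint.brain_conc_total: 2,
    Endpoint.sol_ab40: 3,
    Endpoint.insol_ab40: 4,
    Endpoint.sol_ab42: 5,
    Endpoint.insol_ab42: 6,
}
_DVID_LOOKUP = {v: k for k, v in DVID_CODES.items()}

AB_ENDPOINTS = frozenset(
    {Endpoint.sol_ab40, Endpoint.insol_ab40, Endpoint.sol_ab42, Endpoint.insol_ab42}
)


class Strain(str, enum.Enum):
    c57bl6 = "C57BL/6"
    tg2576 = "Tg2576"
    littermate = "littermate"


class Arm(str, enum.Enum):
    vehicle = "vehicle"
    treated = "treated"
    naive = "naive"


@dataclass(frozen=True)
class UnitConventions:
    """Fixed time-unit conventions.

    ``hours_per_month`` defaults to 730.5 h (365.25 d / 12 × 24 h), which
    places the insoluble-scaling inflection of 7610 h at ≈10.4 months of age.
    """

    hours_per_month: float = 730.5

    def age_to_hours(self, age_months: float) -> float:
        if np.any(np.asarray(age_months) < 0):
            raise ValidationError("age must be non-negative")
        return age_months * self.hours_per_month

    def hours_to_age(self, hours: float) -> float:
        return hours / self.hours_per_month


DEFAULT_CONVENTIONS = UnitConventions()


def age_to_model_time(age_months, conventions: UnitConventions = DEFAULT_CONVENTIONS):
    """Convert age in months to model time (hours since birth)."""
    return conventions.age_to_hours(age_months)


@dataclass(frozen=True)
class DoseEvent:
    time_h: float
    amount: float           # μmol/kg
    route: Route = Route.oral
    vehicle: int | None = 1

    def __post_init__(self):
        if self.time_h < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time_h}")
        if self.amount <= 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.route is Route.oral and self.vehicle not in (1, 2, 3):
            raise ValidationError(f"oral dosing requires vehicle in 1..3, got {self.vehicle}")


@dataclass(frozen=True)
class Observation:
    animal_id: str
    time_h: float
    endpoint: Endpoint
    value: float
    blq_flag: bool = False
    lloq: float = math.nan

    def __post_init__(self):
        if self.value < 0 and not self.blq_flag:
            raise ValidationError(
                f"negative observation without BLQ flag: {self.animal_id} {self.endpoint}"
            )


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    strain: Strain
    age_at_start_months: float
    study_id: str
    arm: Arm

    def __post_init__(self):
        if self.age_at_start_months <= 0:
            raise ValidationError("age_at_start_months must be > 0")


@dataclass
class Dataset:
    """Event-stream container: animals, per-animal dose lists, observations."""

    animals: list[AnimalRecord] = field(default_factory=list)
    doses: dict[str, list[DoseEvent]] = field(default_factory=dict)
    observations: list[Observation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = {a.animal_id for a in self.animals}
        if len(ids) != len(self.animals):
            raise ValidationError("duplicate animal_id")
        for aid in self.doses:
            if aid not in ids:
                raise ValidationError(f"doses for unknown animal {aid!r}")
            times = [d.time_h for d in self.doses[aid]]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ValidationError(f"dose events of {aid!r} not time-ordered")
        strain_of = {a.animal_id: a.strain for a in self.animals}
        for o in self.observations:
            if o.animal_id not in ids:
                raise ValidationError(f"observation for unknown animal {o.animal_id!r}")
            if o.endpoint in AB_ENDPOINTS and strain_of[o.animal_id] is not Strain.tg2576:
                raise ValidationError(
                    f"Aβ endpoint on non-Tg2576 animal {o.animal_id!r}"
                )

    @property
    def animal_index(self) -> dict[str, AnimalRecord]:
        return {a.animal_id: a for a in self.animals}

    def doses_for(self, animal_id: str) -> list[DoseEvent]:
        return self.doses.get(animal_id, [])

    def subset(self, animal_ids) -> "Dataset":
        keep = set(animal_ids)
        return Dataset(
            animals=[a for a in self.animals if a.animal_id in keep],
            doses={k: v for k, v in self.doses.items() if k in keep},
            observations=[o for o in self.observations if o.animal_id in keep],
        )

    def merged_with(self, other: "Dataset") -> "Dataset":
        return Dataset(
            animals=self.animals + other.animals,
            doses={**self.doses, **other.doses},
            observations=self.observations + other.observations,
        )


# ---------------------------------------------------------------------------
# CSV reader / writer (NONMEM-style event records)
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = [
    "ID", "TIME", "DV", "AMT", "EVID", "DVID", "AGE",
    "ROUTE", "VEHICLE", "STUDY", "ARM", "LLOQ",
]


def _parse_route(tok) -> Route:
    key = str(tok).strip().lower()
    if key not in _ROUTE_ALIASES:
        raise ValidationError(f"unknown route {tok!r}")
    return _ROUTE_ALIASES[key]


def read_dataset(path, conventions: UnitConventions = DEFAULT_CONVENTIONS) -> Dataset:
    """Read an event-record CSV into a validated :class:`Dataset`.

    EVID=1 rows become :class:`DoseEvent`, EVID=0 rows :class:`Observation`.
    Missing values are encoded as ``.`` per the NONMEM convention.
    """
    df = pd.read_csv(path, na_values=["."], dtype={"ID": str, "STUDY": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    animals: list[AnimalRecord] = []
    seen: set[str] = set()
    doses: dict[str, list[DoseEvent]] = {}
    observations: list[Observation] = []

    for _, row in df.iterrows():
        aid = str(row["ID"])
        if aid not in seen:
            seen.add(aid)
            strain = Strain(row["STRAIN"]) if "STRAIN" in df.columns and pd.notna(row.get("STRAIN")) else Strain.tg2576
            animals.append(AnimalRecord(
                animal_id=aid,
                strain=strain,
                age_at_start_months=float(row["AGE"]),
                study_id=str(row["STUDY"]),
                arm=Arm(str(row["ARM"])),
            ))
        evid = int(row["EVID"])
        if evid == 1:
            amt = float(row["AMT"])
            if amt <= 0 or not np.isfinite(amt):
                raise ValidationError(f"non-positive AMT {amt} for animal {aid}")
            vehicle = int(row["VEHICLE"]) if pd.notna(row["VEHICLE"]) else None
            doses.setdefault(aid, []).append(DoseEvent(
                time_h=float(row["TIME"]), amount=amt,
                route=_parse_route(row["ROUTE"]), vehicle=vehicle,
            ))
        elif evid == 0:
            dvid = int(row["DVID"])
            if dvid not in _DVID_LOOKUP:
                raise ValidationError(f"unknown DVID {dvid}")
            value = float(row["DV"])
            lloq = float(row["LLOQ"]) if pd.notna(row["LLOQ"]) else math.nan
            blq = bool(np.isfinite(lloq) and value < lloq)
            observations.append(Observation(
                animal_id=aid, time_h=float(row["TIME"]),
                endpoint=_DVID_LOOKUP[dvid], value=value,
                blq_flag=blq, lloq=lloq,
            ))
        else:
            raise ValidationError(f"unsupported EVID {evid}")

    for aid in doses:
        doses[aid].sort(key=lambda d: d.time_h)
    return Dataset(animals=animals, doses=doses, observations=observations)


def to_frame(ds: Dataset) -> pd.DataFrame:
    """Flatten a Dataset back into the event-record table."""
    rows = []
    meta = ds.animal_index
    for a in ds.animals:
        for d in ds.doses_for(a.animal_id):
            rows.append(dict(
                ID=a.animal_id, TIME=d.time_h, DV=np.nan, AMT=d.amount, EVID=1,
                DVID=np.nan, AGE=a.age_at_start_months, ROUTE=d.route.value,
                VEHICLE=d.vehicle, STUDY=a.study_id, ARM=a.arm.value,
                LLOQ=np.nan, STRAIN=a.strain.value,
            ))
    for o in ds.observations:
        a = meta[o.animal_id]
        rows.append(dict(
            ID=o.animal_id, TIME=o.time_h, DV=o.value, AMT=np.nan, EVID=0,
            DVID=DVID_CODES[o.endpoint], AGE=a.age_at_start_months,
            ROUTE=np.nan, VEHICLE=np.nan, STUDY=a.study_id, ARM=a.arm.value,
            LLOQ=o.lloq, STRAIN=a.strain.value,
        ))
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "EVID", "TIME"], kind="stable").reset_index(drop=True)


def write_dataset(ds: Dataset, path) -> None:
    to_frame(ds).to_csv(path, index=False, na_rep=".")


# ---------------------------------------------------------------------------
# BLQ exclusion (M1 method: below-LLOQ rows are dropped before fitting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BLQReport:
    excluded_fraction: dict[Endpoint, float]
    n_excluded: dict[Endpoint, int]
    n_total: dict[Endpoint, int]


def exclude_blq(ds: Dataset, endpoints=None) -> tuple[Dataset, BLQReport]:
    """Drop BLQ-flagged observations for the named endpoints.

    Returns the filtered dataset and a per-endpoint exclusion report.
    Endpoints not named are untouched; ``endpoints=None`` means all.
    """
    if endpoints is None:
        endpoints = set(Endpoint)
    endpoints = {Endpoint(e) for e in endpoints}
    n_total: dict[Endpoint, int] = {e: 0 for e in endpoints}
    n_excl: dict[Endpoint, int] = {e: 0 for e in endpoints}
    kept = []
    for o in ds.observations:
        if o.endpoint in endpoints:
            n_total[o.endpoint] += 1
            if o.blq_flag:
                n_excl[o.endpoint] += 1
                continue
        kept.append(o)
    frac = {
        e: (n_excl[e] / n_total[e] if n_total[e] else 0.0) for e in endpoints
    }
    out = Dataset(animals=list(ds.animals), doses=dict(ds.doses), observations=kept)
    return out, BLQReport(excluded_fraction=frac, n_excluded=n_excl, n_total=n_total)


# ---------------------------------------------------------------------------
# Parameter configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML/JSON parameter configuration keyed by parameter names."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
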