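"""Logistic amyloid-progression model: age-dependent soluble/insoluble
Aβ40 and Aβ42 levels in drug-free Tg2576 mice.

The level at age ``a`` (months) follows a baseline-offset Hill curve

    AP(a) = baseline + (α − baseline) · a^P / (EC_i^P + a^P)

with an initial flat phase in young animals, an exponential-looking rise and
a plateau α reached after ~20 months. EC_i is the age of half-maximal rise
and P the steepness. Each Aβ variant (soluble/insoluble × Aβ40/Aβ42) is
described independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Endpoint, ValidationError


@dataclass
class APParams:
    """Amyloid-progression parameters for one Aβ variant."""

    alpha: float              # pg/mg, upper asymptote (old-age plateau)
    ec_i: float               # months, inflection (half-rise) age
    p: float                  # unitless slope
    baseline: float           # pg/mg, young-age level
    variant: Endpoint = Endpoint.sol_ab40

    def __post_init__(self):
        if not (self.alpha > self.baseline > 0):
            raise ValidationError("require alpha > baseline > 0")
        if self.ec_i <= 0 or self.p <= 0:
            raise ValidationError("ec_i and p must be > 0")

    @classmethod
    def from_config(cls, cfg: dict, variant=Endpoint.sol_ab40) -> "APParams":
        aliases = {"Alpha": "alpha", "EC_i": "ec_i", "P": "p", "Baseline": "baseline"}
        kwargs = {aliases.get(k, k): v for k, v in cfg.items()}
        kwargs.setdefault("variant", variant)
        return cls(**kwargs)


#: reference drug-free progression estimates per variant (pg/mg, months)
DEFAULT_PROGRESSION_PARAMS: dict[Endpoint, APParams] = {
    Endpoint.sol_ab40: APParams(6640.0, 20.0, 6.4, 48.0, Endpoint.sol_ab40),
    Endpoint.insol_ab40: APParams(39900.0, 17.0, 8.3, 29.0, Endpoint.insol_ab40),
    Endpoint.sol_ab42: APParams(2240.0, 18.0, 5.9, 34.0, Endpoint.sol_ab42),
    Endpoint.insol_ab42: APParams(40900.0, 18.0, 6.8, 27.0, Endpoint.insol_ab42),
}

#: progression parameters for soluble Aβ40 as re-estimated inside the
#: integrated drug-effect model (model C)
INTEGRATED_SOL_AB40_PARAMS = APParams(6620.0, 18.1, 7.5, 57.1, Endpoint.sol_ab40)


def ap_level(age_months, params: APParams):
    """Drug-free Aβ level (pg/mg) at a given age (months)."""
    age = np.asarray(age_months, dtype=float)
    if np.any(age < 0):
        raise ValidationError("age must be non-negative")
    frac = age ** params.p / (params.ec_i ** params.p + age ** params.p)
    out = params.baseline + (params.alpha - params.baseline) * frac
    return float(out) if np.ndim(age_months) == 0 else out


def fold_increase(params: APParams, young_level: float) -> float:
    """Plateau-to-young fold increase, α / young level."""
    if young_level <= 0:
        raise ValidationError("young_level must be > 0")
    return params.alpha / young_level


def inflection_age(params: APParams) -> float:
    """Age (months) at which the level is halfway between baseline and α."""
    return params.ec_i
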