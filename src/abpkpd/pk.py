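"""Two-compartment pharmacokinetics of MRK-560 with dose-dependent oral
bioavailability and an instantaneous-equilibrium brain-exposure mapping.

Disposition is linear: first-order absorption (route-specific rate constant)
into a central compartment with clearance CL and volume V2, exchanging with a
peripheral compartment (Q, V3). Doses are in μmol/kg and volumes in L/kg, so
concentrations come out directly in μmol/L. Oral bioavailability with the
standard suspension vehicle saturates with dose:

    F(D) = θ2 + (1 − θ2) / (1 + (θ1·D)^θ3)

which tends to 1 at vanishing dose and to θ2 at high dose; θ1 is allowed to
differ between studies. Brain exposure assumes instantaneous distribution of
unbound drug, so total brain concentration is a fixed multiple θ4 of the
plasma concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import DoseEvent, Route, ValidationError


class ConfigurationError(ValueError):
    pass


@dataclass
class PKParams:
    """Absorption/disposition/bioavailability/brain-partition parameters.

    Defaults are the reference estimates for MRK-560 in mice. ``bsv_omegas``
    holds log-normal between-subject SDs (as CV fractions) used for
    simulation only — estimation of random effects is out of scope.
    """

    ka_po: float = 0.41          # 1/h, oral absorption
    ka_sc: float = 0.81          # 1/h, subcutaneous absorption
    cl: float = 0.12             # L/h/kg
    v2: float = 0.28             # L/kg, central volume
    q: float = 7.6               # L/h/kg, inter-compartmental clearance
    v3: float = 2.9              # L/kg, peripheral volume
    brain_plasma_ratio: float = 0.31   # θ4, total brain:plasma ratio
    fu_pl: float = 0.004         # unbound fraction, plasma
    fu_br: float = 0.0067        # unbound fraction, brain
    f_veh2: float = 1.0
    f_veh3: float = 0.7
    f_sc: float = 0.8
    fdose_theta1: float = 0.01   # study-specific; reference range 0.0001–0.2
    fdose_theta2: float = 0.22   # high-dose asymptote of F(D)
    fdose_theta3: float = 0.5    # shape
    theta1_by_study: dict = field(default_factory=dict)
    bsv_omegas: dict = field(default_factory=dict)  # e.g. {"v2": 1.79, "v3": 0.5, "brain_plasma_ratio": 0.61}
    v_blood_brain: float = 0.013  # fractional blood volume in brain tissue

    def __post_init__(self):
        for name in ("ka_po", "ka_sc", "cl", "v2", "q", "v3", "brain_plasma_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("fu_pl", "fu_br", "f_veh2", "f_veh3", "f_sc"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")

    # rate constants / eigenvalues of the disposition system
    @property
    def k10(self) -> float:
        return self.cl / self.v2

    @property
    def k12(self) -> float:
        return self.q / self.v2

    @property
    def k21(self) -> float:
        return self.q / self.v3

    def lambdas(self) -> tuple[float, float]:
        s = self.k10 + self.k12 + self.k21
        p = self.k10 * self.k21
        disc = np.sqrt(s * s - 4.0 * p)
        l1 = 0.5 * (s + disc)
        l2 = 0.5 * (s - disc)
        return l1, l2

    def theta1_for(self, study_id: str | None) -> float:
        if study_id is not None and study_id in self.theta1_by_study:
            return self.theta1_by_study[study_id]
        return self.fdose_theta1

    def with_bsv(self, rng: np.random.Generator) -> "PKParams":
        """Draw one individual's parameters with log-normal BSV factors."""
        draws = {}
        for name, omega in self.bsv_omegas.items():
            if omega > 0:
                sd = np.sqrt(np.log1p(omega ** 2))  # CV-matched log-normal
                draws[name] = getattr(self, name) * np.exp(rng.normal(0.0, sd))
        return replace(self, **draws) if draws else self

    @classmethod
    def from_config(cls, cfg: dict) -> "PKParams":
        """Build from a config dict accepting the reference parameter names."""
        aliases = {
            "KA_oral": "ka_po", "KA_sc": "ka_sc", "CL": "cl", "V2": "v2",
            "Q": "q", "V3": "v3", "Brain:plasma ratio": "brain_plasma_ratio",
            "theta1": "fdose_theta1", "theta2": "fdose_theta2",
            "theta3": "fdose_theta3", "F_veh2": "f_veh2", "F_veh3": "f_veh3",
            "F_sc": "f_sc", "fu_pl": "fu_pl", "fu_br": "fu_br",
        }
        kwargs = {}
        for key, val in cfg.items():
            name = aliases.get(key, key)
            kwargs[name] = val
        return cls(**kwargs)


@dataclass(frozen=True)
class PKProfile:
    times_h: np.ndarray
    plasma_conc: np.ndarray
    brain_conc_total: np.ndarray


def bioavailability(dose: float, route: Route, vehicle: int | None,
                    params: PKParams, study_id: str | None = None) -> float:
    """Bioavailable fraction for one dose.

    Oral vehicle 1 uses the saturable dose-dependent form; oral vehicles 2/3
    and the s.c. route use fixed fractions; i.v. is complete by definition.
    """
    route = Route(route)
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    if route is Route.iv:
        return 1.0
    if route is Route.sc:
        return params.f_sc
    if route is Route.oral:
        if vehicle == 1:
            th1 = params.theta1_for(study_id)
            th2, th3 = params.fdose_theta2, params.fdose_theta3
            return th2 + (1.0 - th2) / (1.0 + (th1 * dose) ** th3)
        if vehicle == 2:
            return params.f_veh2
        if vehicle == 3:
            return params.f_veh3
    raise ConfigurationError(f"unknown route/vehicle combination: {route}, {vehicle}")


def _absorption_coeffs(ka: float, l1: float, l2: float, k21: float):
    # guard against the (non-physiological here) degenerate ka == lambda case
    if abs(ka - l1) < 1e-12 or abs(ka - l2) < 1e-12:
        ka = ka * (1.0 + 1e-9)
    c1 = (k21 - l1) / ((ka - l1) * (l2 - l1))
    c2 = (k21 - l2) / ((ka - l2) * (l1 - l2))
    c3 = (k21 - ka) / ((l1 - ka) * (l2 - ka))
    return ka, c1, c2, c3


def plasma_concentration(t_h, doses: list[DoseEvent], params: PKParams,
                         study_id: str | None = None) -> np.ndarray:
    """Closed-form plasma concentration (μmol/L) by superposition of doses.

    Right-continuous at dose instants: a dose contributes from its own
    timestamp on. Times before the first dose give 0.
    """
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    out = np.zeros_like(t)
    l1, l2 = params.lambdas()
    k21 = params.k21
    for d in doses:
        tau = t - d.time_h
        active = tau >= 0
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        f = bioavailability(d.amount, d.route, d.vehicle, params, study_id)
        amt = f * d.amount
        if d.route is Route.iv:
            a = (l1 - k21) / (l1 - l2)
            b = (k21 - l2) / (l1 - l2)
            c = (amt / params.v2) * (a * np.exp(-l1 * tau) + b * np.exp(-l2 * tau))
        else:
            ka = params.ka_po if d.route is Route.oral else params.ka_sc
            ka, c1, c2, c3 = _absorption_coeffs(ka, l1, l2, k21)
            c = (amt * ka / params.v2) * (
                c1 * np.exp(-l1 * tau) + c2 * np.exp(-l2 * tau) + c3 * np.exp(-ka * tau)
            )
        out += np.where(active, c, 0.0)
    out = np.maximum(out, 0.0)  # clip tiny negative round-off
    if np.isscalar(t_h):
        return float(out[0])
    return out


def brain_concentration(cp, params: PKParams):
    """Total brain concentration from plasma concentration (instantaneous
    equilibrium): C_br = θ4 · C_p."""
    return params.brain_plasma_ratio * np.asarray(cp, dtype=float) if np.ndim(cp) else params.brain_plasma_ratio * cp


def blood_contamination_correct(brain_measured, cp, params: PKParams):
    """Correct a measured brain concentration for the blood contained in
    unperfused brain tissue (default 1.3% by volume), floored at zero."""
    corrected = np.asarray(brain_measured, dtype=float) - params.v_blood_brain * np.asarray(cp, dtype=float)
    return np.maximum(corrected, 0.0) if np.ndim(corrected) else max(float(corrected), 0.0)


def unbound_concentration(conc_total, fu: float):
    """Unbound concentration from a total concentration and unbound fraction."""
    if not (0 < fu <= 1):
        raise ValidationError("fu must be in (0, 1]")
    return conc_total * fu


def pk_profile(times_h, doses: list[DoseEvent], params: PKParams,
               study_id: str | None = None) -> PKProfile:
    """Plasma and total-brain concentration-time profile."""
    times = np.asarray(times_h, dtype=float)
    cp = plasma_concentration(times, doses, params, study_id)
    return PKProfile(times_h=times, plasma_conc=cp,
                     brain_conc_total=params.brain_plasma_ratio * cp)
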