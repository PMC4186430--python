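"""Integrated PKPD model: age-driven soluble Aβ40 turnover with drug
inhibition of production, feeding insoluble Aβ40 turnover through a
time-dependent scaling function.

State: (A_sol, A_insol) in pg/mg. Model time is hours since birth, so the
progression term is a function of absolute age and study dosing is shifted
by the age at study start.

    dA_sol/dt   = k_out,sol · AP(age) · (1 − I(C_br, A_sol)) − k_out,sol · A_sol
    dA_insol/dt = k_out,insol · (B_insol + SCALE(t) · A_sol) − k_out,insol · A_insol

Production of soluble Aβ40 is tied to the loss rate (K_in,sol = k_out,sol ·
AP(age)) so the drug-free steady state equals the amyloid-progression curve.
Three candidate drug-effect models act on soluble production:

* A (absolute): production reduced by an absolute Hill term
  E_abs·C/(IC50_A + C), clamped at zero;
* B (relative):  I = I_max·C/(IC50 + C) with a fixed IC50;
* C (modified relative): as B but IC50 = A_sol/SL rises with the soluble
  level, so the same exposure inhibits less in older animals.

SCALE(t) = α₂·t^P₂/(EC_i2^P₂ + t^P₂) maps soluble to insoluble production;
its inflection EC_i2 is in hours since birth. Insoluble turnover is ~430×
slower than soluble (half-lives ≈ 30 days vs 38 min), which is why acute
dosing moves soluble but not insoluble Aβ40.

Integration uses a fixed-step RK4 scheme compiled with numba, with segment
boundaries aligned to dose events; the drug forcing term is collapsed per
segment into at most four exponentials, making cost independent of the
number of doses. Accuracy is validated elsewhere against an adaptive stiff
reference integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .datamodel import (
    AnimalRecord,
    DoseEvent,
    Endpoint,
    Route,
    UnitConventions,
    DEFAULT_CONVENTIONS,
    ValidationError,
)
from .pk import PKParams, ConfigurationError, _absorption_coeffs, bioavailability, plasma_concentration
from .progression import APParams, INTEGRATED_SOL_AB40_PARAMS, ap_level


class NumericalError(RuntimeError):
    """Integration failed or produced non-finite state."""


# default step sizes (hours): during/after dosing vs drug-free growth
H_DOSE = 0.05
H_FREE = 1.0

_MODEL_CODES = {"A": 0, "B": 1, "C": 2}


@dataclass
class PDParams:
    """Turnover + drug-effect parameters for the integrated Aβ40 model.

    Defaults are the final model-C estimates; the progression component
    ``ap`` is the soluble-Aβ40 curve re-fitted jointly with the drug data.
    Model A's parameters (``e_abs``, ``ic50_a``) have no published values
    and are configurable; defaults put its absolute effect near 100% of
    young-age production.
    """

    kout_sol: float = 1.1          # 1/h, fixed from literature (t1/2 38 min)
    imax: float = 0.86             # max fractional inhibition (models B/C)
    sl: float = 514.0              # soluble-Aβ-to-IC50 slope (model C)
    ic50_fixed: float | None = None  # μmol/L (model B)
    kout_insol: float = 0.001      # 1/h (t1/2 ~30 days)
    baseline_insol: float = 28.9   # pg/mg
    alpha2: float = 6.5            # upper asymptote of SCALE
    ec_i2: float = 7610.0          # h since birth, SCALE inflection
    p2: float = 9.1                # SCALE slope
    effect_model: str = "C"
    ap: APParams = field(default_factory=lambda: replace(INTEGRATED_SOL_AB40_PARAMS))
    e_abs: float = 60.0            # pg/mg/h, model A absolute effect size
    ic50_a: float = 0.11           # μmol/L, model A IC50
    use_unbound: bool = False      # drive inhibition with unbound brain conc

    def __post_init__(self):
        self.effect_model = str(self.effect_model).upper()
        if self.effect_model not in _MODEL_CODES:
            raise ConfigurationError(f"unknown effect model {self.effect_model!r}")
        if self.kout_sol <= 0 or self.kout_insol <= 0:
            raise ValidationError("turnover rates must be > 0")
        if self.alpha2 <= 0:
            raise ValidationError("alpha2 must be > 0")
        if self.effect_model in ("B", "C") and not (0 < self.imax <= 1):
            raise ValidationError("imax must be in (0, 1] for models B/C")
        if self.effect_model == "C" and (self.sl is None or self.sl <= 0):
            raise ConfigurationError("model C requires a positive slope sl")
        if self.effect_model == "B" and (self.ic50_fixed is None or self.ic50_fixed <= 0):
            raise ConfigurationError("model B requires a positive ic50_fixed")

    @property
    def baseline_sol(self) -> float:
        return self.ap.baseline

    @classmethod
    def from_config(cls, cfg: dict) -> "PDParams":
        """Build from a flat config dict accepting reference parameter names."""
        aliases = {
            "Kout_soluble": "kout_sol", "Kout_sol": "kout_sol",
            "Imax": "imax", "IC50_slope": "sl", "SL": "sl",
            "IC50": "ic50_fixed",
            "Kout_insoluble": "kout_insol", "Kout_insol": "kout_insol",
            "Baseline_insoluble": "baseline_insol",
            "Alpha2": "alpha2", "EC_i2": "ec_i2", "P2": "p2",
        }
        ap_aliases = {"Alpha": "alpha", "EC_i": "ec_i", "P": "p",
                      "Baseline_soluble": "baseline", "Baseline_sol": "baseline"}
        kwargs, ap_kwargs = {}, {}
        for key, val in cfg.items():
            if key in ap_aliases:
                ap_kwargs[ap_aliases[key]] = val
            else:
                kwargs[aliases.get(key, key)] = val
        if ap_kwargs:
            base = replace(INTEGRATED_SOL_AB40_PARAMS)
            kwargs["ap"] = replace(base, **ap_kwargs)
        return cls(**kwargs)

    def _vector(self, hours_per_month: float) -> np.ndarray:
        return np.array([
            self.kout_sol, self.imax,
            self.sl if self.sl is not None else np.nan,
            self.ic50_fixed if self.ic50_fixed is not None else np.nan,
            self.e_abs, self.ic50_a,
            self.ap.alpha, self.ap.ec_i, self.ap.p, self.ap.baseline,
            self.kout_insol, self.baseline_insol,
            self.alpha2, self.ec_i2, self.p2,
            hours_per_month,
        ], dtype=np.float64)


@dataclass(frozen=True)
class PDState:
    a_sol: float
    a_insol: float

    def __post_init__(self):
        if self.a_sol < 0 or self.a_insol < 0:
            raise ValidationError("state must be non-negative")


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories on an absolute-age time axis (hours since birth)."""

    times_h: np.ndarray
    a_sol: np.ndarray
    a_insol: np.ndarray
    c_brain: np.ndarray
    ap_reference: np.ndarray


# ---------------------------------------------------------------------------
# elementary model functions
# ---------------------------------------------------------------------------

def ic50_of_level(a_sol, sl: float):
    """Model-C IC50 (μmol/L) at a given soluble Aβ40 level: IC50 = A_sol/SL."""
    if sl <= 0:
        raise ValidationError("sl must be > 0")
    a = np.asarray(a_sol, dtype=float)
    if np.any(a < 0):
        raise ValidationError("a_sol must be >= 0")
    out = a / sl
    return float(out) if np.ndim(a_sol) == 0 else out


def inhibition(c_brain: float, a_sol: float, params: PDParams) -> float:
    """Drug-effect term: fractional inhibition of soluble production for
    models B/C, or the absolute production-rate decrement (pg/mg/h) for A."""
    if c_brain < 0:
        raise ValidationError("c_brain must be >= 0")
    if params.effect_model == "A":
        return params.e_abs * c_brain / (params.ic50_a + c_brain) if c_brain > 0 else 0.0
    if params.effect_model == "B":
        ic50 = params.ic50_fixed
    else:  # C
        ic50 = ic50_of_level(a_sol, params.sl)
    if c_brain == 0.0:
        return 0.0
    return params.imax * c_brain / (ic50 + c_brain)


def scale_function(t_h, params: PDParams):
    """Soluble→insoluble scaling, a Hill function of hours since birth."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t_h must be >= 0")
    out = params.alpha2 * t ** params.p2 / (params.ec_i2 ** params.p2 + t ** params.p2)
    return float(out) if np.ndim(t_h) == 0 else out


def rhs(t_h: float, state, c_brain: float, params: PDParams,
        conventions: UnitConventions = DEFAULT_CONVENTIONS) -> np.ndarray:
    """Time derivative of (A_sol, A_insol); reference (uncompiled) form."""
    a_sol = max(float(state[0]), 0.0)
    a_insol = float(state[1])
    age_m = t_h / conventions.hours_per_month
    ap = ap_level(age_m, params.ap)
    if params.effect_model == "A":
        prod = max(ap * params.kout_sol - inhibition(c_brain, a_sol, params), 0.0)
    else:
        prod = params.kout_sol * ap * (1.0 - inhibition(c_brain, a_sol, params))
    dsol = prod - params.kout_sol * a_sol
    dinsol = params.kout_insol * (params.baseline_insol + scale_function(t_h, params) * a_sol) \
        - params.kout_insol * a_insol
    return np.array([dsol, dinsol])


# ---------------------------------------------------------------------------
# compiled integration engine
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _rhs_jit(t, y0, y1, conc, pdv, model_code):
    kout_sol = pdv[0]
    a_sol = y0 if y0 > 0.0 else 0.0
    age = t / pdv[15]
    # progression level at this age
    if age <= 0.0:
        ap = pdv[9]
    else:
        g = age ** pdv[8]
        ap = pdv[9] + (pdv[6] - pdv[9]) * g / (pdv[7] ** pdv[8] + g)
    if model_code == 0:      # A: absolute decrement of production
        eff = pdv[4] * conc / (pdv[5] + conc) if conc > 0.0 else 0.0
        prod = kout_sol * ap - eff
        if prod < 0.0:
            prod = 0.0
    else:
        if conc > 0.0:
            if model_code == 1:   # B: fixed IC50
                ic50 = pdv[3]
            else:                 # C: level-dependent IC50
                ic50 = a_sol / pdv[2]
            inh = pdv[1] * conc / (ic50 + conc)
        else:
            inh = 0.0
        prod = kout_sol * ap * (1.0 - inh)
    dsol = prod - kout_sol * a_sol
    if t <= 0.0:
        scale = 0.0
    else:
        tp = t ** pdv[14]
        scale = pdv[12] * tp / (pdv[13] ** pdv[14] + tp)
    dinsol = pdv[10] * (pdv[11] + scale * a_sol) - pdv[10] * y1
    return dsol, dinsol


@njit(cache=True, fastmath=False)
def _conc_at(t, seg_start, seg_coefs, rates):
    c = 0.0
    for m in range(rates.shape[0]):
        c += seg_coefs[m] * math.exp(-rates[m] * (t - seg_start))
    return c if c > 0.0 else 0.0


@njit(cache=True, fastmath=False)
def _integrate_path(knots, n_steps, seg_coefs, rates, out_mask, y0_sol, y0_insol,
                    pdv, model_code):
    n_out = 0
    for i in range(out_mask.shape[0]):
        if out_mask[i]:
            n_out += 1
    out = np.empty((n_out, 2))
    k = 0
    ys = y0_sol
    yi = y0_insol
    if out_mask[0]:
        out[k, 0] = ys
        out[k, 1] = yi
        k += 1
    for s in range(knots.shape[0] - 1):
        t0 = knots[s]
        t1 = knots[s + 1]
        n = n_steps[s]
        h = (t1 - t0) / n
        cs = seg_coefs[s]
        for i in range(n):
            t = t0 + i * h
            c1 = _conc_at(t, t0, cs, rates)
            c2 = _conc_at(t + 0.5 * h, t0, cs, rates)
            c3 = _conc_at(t + h, t0, cs, rates)
            k1s, k1i = _rhs_jit(t, ys, yi, c1, pdv, model_code)
            k2s, k2i = _rhs_jit(t + 0.5 * h, ys + 0.5 * h * k1s, yi + 0.5 * h * k1i, c2, pdv, model_code)
            k3s, k3i = _rhs_jit(t + 0.5 * h, ys + 0.5 * h * k2s, yi + 0.5 * h * k2i, c2, pdv, model_code)
            k4s, k4i = _rhs_jit(t + h, ys + h * k3s, yi + h * k3i, c3, pdv, model_code)
            ys = ys + h / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            yi = yi + h / 6.0 * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
            if ys < 0.0:
                ys = 0.0
            if yi < 0.0:
                yi = 0.0
        if out_mask[s + 1]:
            out[k, 0] = ys
            out[k, 1] = yi
            k += 1
    return out


def _dose_terms(doses_abs: list[DoseEvent], pk: PKParams, study_id, drive_scale: float):
    """Per-dose exponential terms of the brain drug concentration.

    Returns (dose_times, term_coefs[n,4], rates[4]) with fixed rate slots
    (λ1, λ2, ka_po, ka_sc); each dose populates up to three slots. Term
    coefficients are pre-scaled by ``drive_scale`` (the brain:plasma ratio,
    optionally times the brain unbound fraction).
    """
    l1, l2 = pk.lambdas()
    rates = np.array([l1, l2, pk.ka_po, pk.ka_sc], dtype=np.float64)
    n = len(doses_abs)
    times = np.empty(n)
    coefs = np.zeros((n, 4))
    for j, d in enumerate(doses_abs):
        times[j] = d.time_h
        f = bioavailability(d.amount, d.route, d.vehicle, pk, study_id)
        amt = f * d.amount
        if d.route is Route.iv:
            a = (l1 - pk.k21) / (l1 - l2)
            b = (pk.k21 - l2) / (l1 - l2)
            coefs[j, 0] = drive_scale * (amt / pk.v2) * a
            coefs[j, 1] = drive_scale * (amt / pk.v2) * b
        else:
            ka = pk.ka_po if d.route is Route.oral else pk.ka_sc
            ka_eff, c1, c2, c3 = _absorption_coeffs(ka, l1, l2, pk.k21)
            pref = drive_scale * amt * ka_eff / pk.v2
            coefs[j, 0] = pref * c1
            coefs[j, 1] = pref * c2
            slot = 2 if d.route is Route.oral else 3
            coefs[j, slot] += pref * c3
    order = np.argsort(times, kind="stable")
    return times[order], coefs[order], rates


def _solve(dose_times, dose_coefs, rates, t0: float, y0, t_eval,
           pdv, model_code: int, h_dose: float = H_DOSE, h_free: float = H_FREE):
    """Integrate from t0 to max(t_eval), returning states at t_eval.

    Segment boundaries are the dose times and evaluation points; within a
    segment the active dose set is frozen (right-continuous at iv doses) and
    collapsed into the four rate slots.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size == 0:
        return np.empty((0, 2))
    t_end = float(t_eval.max())
    if np.any(t_eval < t0 - 1e-9):
        raise ValidationError("evaluation time before integration start")
    inner = dose_times[(dose_times > t0) & (dose_times < t_end)]
    knots = np.unique(np.concatenate([[t0, t_end], inner, t_eval]))
    n_seg = knots.size - 1
    seg_coefs = np.zeros((n_seg, 4))
    n_steps = np.empty(n_seg, dtype=np.int64)
    for s in range(n_seg):
        start, stop = knots[s], knots[s + 1]
        n_active = int(np.searchsorted(dose_times, start, side="right"))
        if n_active > 0:
            dt = start - dose_times[:n_active]
            # collapse active doses onto the shared rate slots
            seg_coefs[s] = np.einsum("jm,jm->m", dose_coefs[:n_active],
                                     np.exp(-np.outer(dt, rates)).reshape(n_active, 4))
            h = h_dose
        else:
            h = h_free
        n_steps[s] = max(1, int(np.ceil((stop - start) / h)))
    out_mask = np.isin(knots, t_eval)
    states = _integrate_path(knots, n_steps, seg_coefs, rates, out_mask,
                             float(y0[0]), float(y0[1]), pdv, model_code)
    if not np.all(np.isfinite(states)):
        raise NumericalError("non-finite state encountered during integration")
    # map back to requested order (t_eval may be unsorted / contain repeats)
    knot_out = knots[out_mask]
    idx = np.searchsorted(knot_out, t_eval)
    return states[idx]


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def initial_state(pd_params: PDParams) -> np.ndarray:
    """Drug-free steady state at birth: (baseline_sol, baseline_insol)."""
    return np.array([pd_params.ap.baseline, pd_params.baseline_insol])


def simulate(animal: AnimalRecord, doses: list[DoseEvent], pk_params: PKParams,
             pd_params: PDParams, t_eval_h=None, *,
             conventions: UnitConventions = DEFAULT_CONVENTIONS,
             h_dose: float = H_DOSE, h_free: float = H_FREE) -> SimulationResult:
    """Simulate one animal's soluble/insoluble Aβ40 trajectories.

    Integration starts at birth from baseline initial conditions; dose times
    (hours since study start) are shifted by the age at study start.
    ``t_eval_h`` is in hours since study start; the result's time axis is
    absolute age in hours. The drug-free reference trajectory is computed
    with the same integrator and zero doses.
    """
    start_h = conventions.age_to_hours(animal.age_at_start_months)
    doses = sorted(doses, key=lambda d: d.time_h)
    if t_eval_h is None:
        last = doses[-1].time_h if doses else 0.0
        t_eval_h = np.linspace(0.0, last + 120.0, 481)
    t_eval_h = np.atleast_1d(np.asarray(t_eval_h, dtype=float))
    t_abs = start_h + t_eval_h

    doses_abs = [replace(d, time_h=start_h + d.time_h) for d in doses]
    drive = pk_params.brain_plasma_ratio * (pk_params.fu_br if pd_params.use_unbound else 1.0)
    dose_t, dose_c, rates = _dose_terms(doses_abs, pk_params, animal.study_id, drive)
    pdv = pd_params._vector(conventions.hours_per_month)
    code = _MODEL_CODES[pd_params.effect_model]
    y0 = initial_state(pd_params)

    states = _solve(dose_t, dose_c, rates, 0.0, y0, t_abs, pdv, code, h_dose, h_free)
    ref = _solve(np.empty(0), np.empty((0, 4)), rates, 0.0, y0, t_abs, pdv, code,
                 h_dose, h_free)
    cp = plasma_concentration(t_abs, doses_abs, pk_params, animal.study_id)
    return SimulationResult(
        times_h=t_abs,
        a_sol=states[:, 0],
        a_insol=states[:, 1],
        c_brain=pk_params.brain_plasma_ratio * cp,
        ap_reference=ref[:, 0],
    )


def average_soluble_reduction(result: SimulationResult, treatment_window) -> float:
    """Time-averaged percent reduction of soluble Aβ40 from the drug-free
    progression over a window (absolute-age hours)."""
    t0, t1 = float(treatment_window[0]), float(treatment_window[1])
    mask = (result.times_h >= t0) & (result.times_h <= t1)
    if t1 <= t0 or mask.sum() < 2:
        raise ValidationError("treatment window empty or outside the simulated span")
    t = result.times_h[mask]
    red = 100.0 * (1.0 - result.a_sol[mask] / result.ap_reference[mask])
    return float(np.trapezoid(red, t) / (t[-1] - t[0]))
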