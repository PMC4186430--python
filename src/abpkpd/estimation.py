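"""Pooled maximum-likelihood estimation for the PK/progression/PKPD models.

Estimation is naive-pooled: all observations share fixed effects plus a
per-endpoint residual error model, with no subject-level random effects
(terminal Aβ sampling is destructive, so between-subject and residual
variability are confounded at the PD level anyway). The objective function
value (OFV) is −2·log-likelihood, comparable across nested models on the
same data.

Residual variances are concentrated out of the likelihood (profile MLE)
unless an explicit SD is supplied. Positivity of rate/scale parameters is
enforced by log-transforming during optimisation; fractions use a logit
transform. Standard errors come from the numerically differentiated
observed-information matrix at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import approx_fprime, minimize

from .datamodel import (
    Arm,
    Dataset,
    DEFAULT_CONVENTIONS,
    Endpoint,
    UnitConventions,
    ValidationError,
)
from .pk import PKParams
from .pkpd import (
    _MODEL_CODES,
    _dose_terms,
    _solve,
    PDParams,
    initial_state,
)
from .progression import APParams, ap_level


_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12


@dataclass
class ErrorModel:
    """Residual error model for one endpoint.

    ``sd`` is the additive SD (endpoint units), the proportional CV
    (fraction), or the log-scale SD, depending on ``kind``; ``None`` means
    the SD is concentrated out by maximum likelihood.
    """

    kind: str = "proportional"
    sd: float | None = None

    def __post_init__(self):
        if self.kind not in ("additive", "proportional", "additive_log"):
            raise ValidationError(f"unknown error model kind {self.kind!r}")
        if self.sd is not None and self.sd <= 0:
            raise ValidationError("sd must be > 0")


@dataclass
class FitResult:
    estimates: dict
    standard_errors: dict
    ofv: float
    n_obs: int
    converged: bool
    fixed: frozenset
    trace: list = field(default_factory=list)
    message: str = ""
    data_signature: tuple = ()
    residual_sd: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.estimates) - len(self.fixed & set(self.estimates))


@dataclass
class ModelSpec:
    """A fit problem: predictions aligned with a frozen observation vector."""

    name: str
    predict: Callable[[dict], np.ndarray]
    obs_values: np.ndarray
    obs_endpoints: list[Endpoint]
    param_names: list[str]
    transforms: dict
    bounds: dict
    fixed: dict
    data_signature: tuple = ()

    def __post_init__(self):
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if not self.data_signature:
            self.data_signature = (
                self.obs_values.size,
                float(np.round(self.obs_values.sum(), 6)),
            )
        grouped: dict[Endpoint, list[int]] = {}
        for i, e in enumerate(self.obs_endpoints):
            grouped.setdefault(e, []).append(i)
        self._groups = {e: np.asarray(idx) for e, idx in grouped.items()}

    @property
    def free_names(self) -> list[str]:
        return [p for p in self.param_names if p not in self.fixed]


def _group_ofv(y: np.ndarray, f: np.ndarray, err: ErrorModel) -> tuple[float, float]:
    """(−2 log L, fitted sd) for one endpoint group."""
    n = y.size
    if err.kind == "additive":
        r2 = (y - f) ** 2
        if err.sd is None:
            s2 = max(float(r2.mean()), 1e-300)
            return n * (_LOG2PI + math.log(s2) + 1.0), math.sqrt(s2)
        s2 = err.sd ** 2
        return float(n * (_LOG2PI + math.log(s2)) + r2.sum() / s2), err.sd
    if err.kind == "proportional":
        if np.any(f <= 0):
            return _PENALTY, math.nan
        r2 = ((y - f) / f) ** 2
        logf2 = 2.0 * float(np.log(f).sum())
        if err.sd is None:
            s2 = max(float(r2.mean()), 1e-300)
            return n * (_LOG2PI + math.log(s2) + 1.0) + logf2, math.sqrt(s2)
        s2 = err.sd ** 2
        return float(n * (_LOG2PI + math.log(s2)) + logf2 + r2.sum() / s2), err.sd
    # additive_log: Gaussian on log(y), Jacobian included so OFVs stay
    # comparable across error models
    if np.any(f <= 0) or np.any(y <= 0):
        return _PENALTY, math.nan
    z2 = (np.log(y) - np.log(f)) ** 2
    logy2 = 2.0 * float(np.log(y).sum())
    if err.sd is None:
        s2 = max(float(z2.mean()), 1e-300)
        return n * (_LOG2PI + math.log(s2) + 1.0) + logy2, math.sqrt(s2)
    s2 = err.sd ** 2
    return float(n * (_LOG2PI + math.log(s2)) + logy2 + z2.sum() / s2), err.sd


def negloglik(params: dict, model: ModelSpec, error) -> float:
    """OFV (−2 log-likelihood) of the observations under the error model.

    ``error`` is an :class:`ErrorModel` or a per-endpoint mapping.
    """
    ofv, _ = _negloglik_detail(params, model, error)
    return ofv


def _negloglik_detail(params, model, error):
    try:
        f = np.asarray(model.predict(params), dtype=float)
    except (ValidationError, FloatingPointError, OverflowError):
        return _PENALTY, {}
    if f.shape != model.obs_values.shape or not np.all(np.isfinite(f)):
        return _PENALTY, {}
    total, sds = 0.0, {}
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        for e, idx in model._groups.items():
            err = error[e] if isinstance(error, dict) else error
            ofv, sd = _group_ofv(model.obs_values[idx], f[idx], err)
            total += ofv
            sds[e] = sd
    return total, sds


# ---------------------------------------------------------------------------
# transform machinery and the generic fitter
# ---------------------------------------------------------------------------

def _to_z(value: float, kind: str) -> float:
    if kind == "log":
        return math.log(value)
    if kind == "logit":
        v = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(v / (1.0 - v))
    return value


def _from_z(z: float, kind: str) -> float:
    if kind == "log":
        return math.exp(z)
    if kind == "logit":
        return 1.0 / (1.0 + math.exp(-z))
    return z


def fit_model(model: ModelSpec, error, init: dict, *, n_starts: int = 1,
              seed: int = 0, maxiter: int = 300, ftol: float = 1e-10) -> FitResult:
    """Maximise the pooled likelihood with bounded quasi-Newton iterations.

    Start 1 is ``init``; further starts perturb it (log-uniformly within
    ±10× for log-scale parameters). The best OFV wins, ties broken by order.
    """
    free = model.free_names
    z0 = np.array([_to_z(init[p], model.transforms.get(p, "log")) for p in free])
    zbounds = []
    for p in free:
        kind = model.transforms.get(p, "log")
        lo, hi = model.bounds.get(p, (None, None))
        zbounds.append((
            None if lo is None else _to_z(lo, kind),
            None if hi is None else _to_z(hi, kind),
        ))

    def unpack(z) -> dict:
        params = dict(model.fixed)
        for p, zi in zip(free, z):
            params[p] = _from_z(zi, model.transforms.get(p, "log"))
        return params

    def objective(z) -> float:
        val = negloglik(unpack(z), model, error)
        return val if np.isfinite(val) else _PENALTY

    rng = np.random.default_rng(seed)
    starts = [z0]
    for _ in range(n_starts - 1):
        pert = rng.uniform(-1.0, 1.0, size=z0.size)
        zi = z0 + np.where(
            [model.transforms.get(p, "log") == "log" for p in free],
            pert * math.log(10.0), pert,
        )
        zi = np.array([
            np.clip(v, lo if lo is not None else -np.inf,
                    hi if hi is not None else np.inf)
            for v, (lo, hi) in zip(zi, zbounds)
        ])
        starts.append(zi)

    best, best_trace = None, []
    for zstart in starts:
        trace: list[float] = []

        def cb(intermediate_result):
            trace.append(float(intermediate_result.fun))

        res = minimize(objective, zstart, method="L-BFGS-B", bounds=zbounds,
                       callback=cb, options={"maxiter": maxiter, "ftol": ftol})
        if best is None or res.fun < best.fun:
            best, best_trace = res, trace

    params = unpack(best.x)
    ofv, sds = _negloglik_detail(params, model, error)
    bound_hit = {
        p: (lo is not None and abs(zi - lo) < 1e-8) or
           (hi is not None and abs(zi - hi) < 1e-8)
        for p, zi, (lo, hi) in zip(free, best.x, zbounds)
    }
    return FitResult(
        estimates=params,
        standard_errors={},
        ofv=float(ofv),
        n_obs=model.obs_values.size,
        converged=bool(best.success and np.isfinite(ofv)),
        fixed=frozenset(model.fixed),
        trace=best_trace,
        message=str(best.message),
        data_signature=model.data_signature,
        residual_sd=sds,
        extra={"n_starts": n_starts, "bound_hit": bound_hit,
               "model_name": model.name},
    )


def standard_errors(fit: FitResult, model: ModelSpec, error,
                    rel_step: float = 1e-4) -> dict:
    """SEs from the observed information (numerical Hessian of the OFV).

    Computed on the natural parameter scale with central differences.
    A singular information matrix flags the SEs unavailable (NaN).
    """
    free = model.free_names
    x0 = np.array([fit.estimates[p] for p in free])
    steps = np.maximum(np.abs(x0) * rel_step, 1e-10)

    def f(x):
        params = dict(fit.estimates)
        params.update(dict(zip(free, x)))
        return negloglik(params, model, error)

    k = len(free)
    hess = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                val = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / steps[i] ** 2
            else:
                val = (f(x0 + ei + ej) - f(x0 + ei - ej)
                       - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4.0 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = val
    ses = {}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        for p, v in zip(free, diag):
            ses[p] = math.sqrt(v)
        fit.extra["se_available"] = True
    except np.linalg.LinAlgError:
        ses = {p: math.nan for p in free}
        fit.extra["se_available"] = False
    fit.standard_errors = ses
    return ses


def compare_models(fits: list[FitResult]):
    """Rank fits of the same dataset by OFV (lower is better).

    Returns a list of dicts with name, ofv, number of free parameters and
    ΔOFV from the best model.
    """
    if not fits:
        raise ValidationError("no fits to compare")
    sig = fits[0].data_signature
    for fr in fits[1:]:
        if fr.data_signature != sig:
            raise ValidationError("fits were not computed on the same dataset")
    ranked = sorted(fits, key=lambda fr: fr.ofv)
    best = ranked[0].ofv
    return [
        {
            "name": fr.extra.get("model_name", "?"),
            "ofv": fr.ofv,
            "n_free": fr.n_free,
            "delta_ofv": fr.ofv - best,
            "converged": fr.converged,
        }
        for fr in ranked
    ]


# ---------------------------------------------------------------------------
# progression fit
# ---------------------------------------------------------------------------

def _terminal_ages(ds: Dataset, obs_list, conventions) -> np.ndarray:
    meta = ds.animal_index
    return np.array([
        meta[o.animal_id].age_at_start_months + o.time_h / conventions.hours_per_month
        for o in obs_list
    ])


def build_ap_model(ds: Dataset, variant: Endpoint,
                   conventions: UnitConventions = DEFAULT_CONVENTIONS,
                   control_only: bool = True) -> ModelSpec:
    """Fit problem for the logistic progression on drug-free data."""
    variant = Endpoint(variant)
    meta = ds.animal_index
    obs = [
        o for o in ds.observations
        if o.endpoint is variant and not o.blq_flag
        and (not control_only or meta[o.animal_id].arm in (Arm.vehicle, Arm.naive))
    ]
    if not obs:
        raise ValidationError(f"no usable observations for {variant}")
    ages = _terminal_ages(ds, obs, conventions)
    if np.unique(np.round(ages, 6)).size < 4:
        raise ValidationError(
            "progression fit needs at least 4 distinct termination ages")
    values = np.array([o.value for o in obs])

    def predict(params: dict) -> np.ndarray:
        ap = APParams(alpha=params["alpha"], ec_i=params["ec_i"], p=params["p"],
                      baseline=params["baseline"], variant=variant)
        return ap_level(ages, ap)

    return ModelSpec(
        name=f"ap_{variant.value}",
        predict=predict,
        obs_values=values,
        obs_endpoints=[variant] * len(obs),
        param_names=["alpha", "ec_i", "p", "baseline"],
        transforms={p: "log" for p in ("alpha", "ec_i", "p", "baseline")},
        bounds={"alpha": (1.0, 1e7), "ec_i": (0.5, 80.0), "p": (0.2, 60.0),
                "baseline": (1e-2, 1e5)},
        fixed={},
    )


def _ap_init_from_data(ages: np.ndarray, values: np.ndarray) -> dict:
    order = np.argsort(ages)
    v = values[order]
    young = v[: max(3, v.size // 5)]
    old = v[-max(3, v.size // 5):]
    baseline = max(float(np.median(young)), 1e-2)
    alpha = max(float(np.median(old)), baseline * 1.5 + 1.0)
    return {"alpha": alpha, "ec_i": float(np.median(ages)), "p": 5.0,
            "baseline": baseline}


def fit_ap(ds: Dataset, variant: Endpoint, *, init: dict | None = None,
           n_starts: int = 10, seed: int = 0,
           error: ErrorModel | None = None,
           conventions: UnitConventions = DEFAULT_CONVENTIONS,
           control_only: bool = True, compute_se: bool = False) -> FitResult:
    """Fit the logistic progression to cross-sectional drug-free data."""
    model = build_ap_model(ds, variant, conventions, control_only)
    error = error or ErrorModel("proportional")
    if init is None:
        meta = ds.animal_index
        obs = [
            o for o in ds.observations
            if o.endpoint is Endpoint(variant) and not o.blq_flag
            and (not control_only or meta[o.animal_id].arm in (Arm.vehicle, Arm.naive))
        ]
        ages = _terminal_ages(ds, obs, conventions)
        init = _ap_init_from_data(ages, np.array([o.value for o in obs]))
    fit = fit_model(model, error, init, n_starts=n_starts, seed=seed)
    if compute_se:
        standard_errors(fit, model, error)
    return fit


# ---------------------------------------------------------------------------
# integrated PKPD fit
# ---------------------------------------------------------------------------

class PKPDPredictor:
    """Design-grouped prediction engine for the integrated Aβ40 model.

    Animals sharing a study, start age and dosing history form one design;
    each design is integrated once per likelihood evaluation, at the ages
    where its animals were sampled. Drug-free arms (vehicle/naive) share a
    single from-birth integration. PK parameters are fixed, so the
    exponential dose terms are precompiled per design.
    """

    _AB40 = (Endpoint.sol_ab40, Endpoint.insol_ab40)

    def __init__(self, ds: Dataset, pk_params: PKParams,
                 conventions: UnitConventions = DEFAULT_CONVENTIONS,
                 use_unbound: bool = False,
                 h_dose: float = 0.05, h_free: float = 1.0):
        self.conventions = conventions
        self.h_dose, self.h_free = h_dose, h_free
        hpm = conventions.hours_per_month
        meta = ds.animal_index
        obs = [o for o in ds.observations
               if o.endpoint in self._AB40 and not o.blq_flag]
        if not obs:
            raise ValidationError("no Aβ40 observations to fit")
        self.obs_values = np.array([o.value for o in obs])
        self.obs_endpoints = [o.endpoint for o in obs]
        self._state_col = np.array(
            [0 if o.endpoint is Endpoint.sol_ab40 else 1 for o in obs])

        drive = pk_params.brain_plasma_ratio * (pk_params.fu_br if use_unbound else 1.0)
        designs: dict[tuple, dict] = {}
        free_times: list[float] = []
        free_rows: list[tuple[int, float]] = []  # (obs index, abs age h)
        for i, o in enumerate(obs):
            a = meta[o.animal_id]
            dlist = tuple(ds.doses_for(o.animal_id))
            t_abs = a.age_at_start_months * hpm + o.time_h
            if not dlist:
                free_times.append(t_abs)
                free_rows.append((i, t_abs))
                continue
            key = (a.study_id, round(a.age_at_start_months, 9), dlist)
            d = designs.setdefault(key, {
                "start_h": a.age_at_start_months * hpm,
                "study_id": a.study_id, "doses": dlist, "rows": [],
            })
            d["rows"].append((i, t_abs))

        self._designs = []
        for d in designs.values():
            doses_abs = [replace(ev, time_h=d["start_h"] + ev.time_h)
                         for ev in d["doses"]]
            dose_t, dose_c, rates = _dose_terms(doses_abs, pk_params,
                                                d["study_id"], drive)
            idx = np.array([r[0] for r in d["rows"]])
            times = np.array([r[1] for r in d["rows"]])
            self._designs.append({
                "dose_t": dose_t, "dose_c": dose_c, "rates": rates,
                "start_h": d["start_h"], "obs_idx": idx, "obs_t": times,
            })
            free_times.append(d["start_h"])
        self._rates0 = (self._designs[0]["rates"] if self._designs
                        else np.array([1.0, 0.1, 0.4, 0.8]))
        self._free_t = np.unique(np.asarray(free_times)) if free_times else np.empty(0)
        self._free_rows = free_rows

    def predict(self, pd_params: PDParams) -> np.ndarray:
        pdv = pd_params._vector(self.conventions.hours_per_month)
        code = _MODEL_CODES[pd_params.effect_model]
        y0 = initial_state(pd_params)
        out = np.empty_like(self.obs_values)
        if self._free_t.size:
            states = _solve(np.empty(0), np.empty((0, 4)), self._rates0, 0.0,
                            y0, self._free_t, pdv, code, self.h_dose, self.h_free)
            lookup = dict(zip(self._free_t, range(self._free_t.size)))
            for i, t_abs in self._free_rows:
                out[i] = states[lookup[t_abs], self._state_col[i]]
            start_states = {t: states[j] for t, j in lookup.items()}
        else:
            start_states = {}
        for d in self._designs:
            y_start = start_states.get(d["start_h"])
            if y_start is None:
                y_start = _solve(np.empty(0), np.empty((0, 4)), d["rates"], 0.0,
                                 y0, np.array([d["start_h"]]), pdv, code,
                                 self.h_dose, self.h_free)[0]
            st = _solve(d["dose_t"], d["dose_c"], d["rates"], d["start_h"],
                        y_start, d["obs_t"], pdv, code, self.h_dose, self.h_free)
            for row, (i,) in zip(st, zip(d["obs_idx"])):
                out[i] = row[self._state_col[i]]
        return out


_PKPD_FREE = {
    "A": ["alpha", "ec_i", "p", "baseline_sol", "e_abs", "ic50_a",
          "kout_insol", "alpha2", "ec_i2", "p2"],
    "B": ["alpha", "ec_i", "p", "baseline_sol", "imax", "ic50_fixed",
          "kout_insol", "alpha2", "ec_i2", "p2"],
    "C": ["alpha", "ec_i", "p", "baseline_sol", "imax", "sl",
          "kout_insol", "alpha2", "ec_i2", "p2"],
}

_PKPD_BOUNDS = {
    "alpha": (10.0, 1e6), "ec_i": (1.0, 80.0), "p": (0.5, 60.0),
    "baseline_sol": (0.1, 1e4), "imax": (0.01, 1.0), "sl": (1.0, 1e5),
    "ic50_fixed": (1e-5, 1e3), "e_abs": (1e-3, 1e5), "ic50_a": (1e-5, 1e3),
    "kout_insol": (1e-6, 1.0), "alpha2": (1e-3, 1e3),
    "ec_i2": (100.0, 1e6), "p2": (0.5, 60.0),
}


def build_pkpd_model(ds: Dataset, pk_params: PKParams, effect_model: str = "C",
                     *, fixed: dict | None = None,
                     conventions: UnitConventions = DEFAULT_CONVENTIONS,
                     use_unbound: bool = False,
                     h_dose: float = 0.05, h_free: float = 1.0) -> ModelSpec:
    """Fit problem for the integrated soluble/insoluble Aβ40 model.

    ``fixed`` maps parameter names to frozen values; the soluble loss rate
    and the insoluble baseline are frozen by default (the former from
    literature, the latter having no reported uncertainty).
    """
    effect_model = str(effect_model).upper()
    predictor = PKPDPredictor(ds, pk_params, conventions, use_unbound,
                              h_dose, h_free)
    fixed = dict(fixed or {})
    fixed.setdefault("kout_sol", 1.1)
    fixed.setdefault("baseline_insol", 28.9)
    free = [p for p in _PKPD_FREE[effect_model] if p not in fixed]
    names = list(dict.fromkeys(list(fixed) + _PKPD_FREE[effect_model]))

    def predict(params: dict) -> np.ndarray:
        ap = APParams(alpha=params["alpha"], ec_i=params["ec_i"], p=params["p"],
                      baseline=params["baseline_sol"], variant=Endpoint.sol_ab40)
        kwargs = dict(
            kout_sol=params["kout_sol"], kout_insol=params["kout_insol"],
            baseline_insol=params["baseline_insol"], alpha2=params["alpha2"],
            ec_i2=params["ec_i2"], p2=params["p2"], effect_model=effect_model,
            ap=ap, use_unbound=use_unbound,
        )
        if effect_model == "A":
            kwargs.update(e_abs=params["e_abs"], ic50_a=params["ic50_a"])
        elif effect_model == "B":
            kwargs.update(imax=params["imax"], ic50_fixed=params["ic50_fixed"])
        else:
            kwargs.update(imax=params["imax"], sl=params["sl"])
        return predictor.predict(PDParams(**kwargs))

    transforms = {p: "log" for p in names}
    transforms["imax"] = "logit"
    return ModelSpec(
        name=f"pkpd_{effect_model}",
        predict=predict,
        obs_values=predictor.obs_values,
        obs_endpoints=predictor.obs_endpoints,
        param_names=names,
        transforms=transforms,
        bounds=dict(_PKPD_BOUNDS),
        fixed=fixed,
    )


def _staged_init(ds: Dataset, effect_model: str, conventions,
                 seed: int) -> tuple[dict, dict]:
    """Data-driven starting values: progression fits on control arms first.

    Returns (init for free params, values for default-fixed params).
    """
    hpm = conventions.hours_per_month
    try:
        sol = fit_ap(ds, Endpoint.sol_ab40, n_starts=4, seed=seed,
                     conventions=conventions)
        ap_init = {
            "alpha": sol.estimates["alpha"], "ec_i": sol.estimates["ec_i"],
            "p": sol.estimates["p"], "baseline_sol": sol.estimates["baseline"],
        }
    except ValidationError:
        # too few control ages to stage the progression fit — neutral start
        ap_init = {"alpha": 5000.0, "ec_i": 18.0, "p": 6.0,
                   "baseline_sol": 50.0}
    init = {
        **ap_init,
        "kout_insol": 0.002, "alpha2": 6.0, "ec_i2": 10.0 * hpm, "p2": 8.0,
    }
    fixed_vals = {"baseline_insol": 28.9}
    try:
        insol = fit_ap(ds, Endpoint.insol_ab40, n_starts=4, seed=seed + 1,
                       conventions=conventions)
        if insol.converged:
            est = insol.estimates
            init["alpha2"] = max(
                (est["alpha"] - est["baseline"]) / max(init["alpha"], 1.0), 1e-2)
            init["ec_i2"] = est["ec_i"] * hpm
            init["p2"] = est["p"]
            fixed_vals["baseline_insol"] = est["baseline"]
    except ValidationError:
        pass
    if effect_model == "A":
        init.update(e_abs=0.5 * 1.1 * init["baseline_sol"], ic50_a=1.0)
    elif effect_model == "B":
        init.update(imax=0.5, ic50_fixed=1.0)
    else:
        init.update(imax=0.5, sl=100.0)
    return init, fixed_vals


def fit_pkpd(ds: Dataset, pk_params: PKParams, effect_model: str = "C", *,
             init: dict | None = None, fixed: dict | None = None,
             n_starts: int = 1, seed: int = 0,
             conventions: UnitConventions = DEFAULT_CONVENTIONS,
             use_unbound: bool = False, compute_se: bool = False,
             h_dose: float = 0.1, maxiter: int = 300) -> FitResult:
    """Fit the integrated PKPD model (pooled likelihood, k_out,sol fixed).

    Starting values are staged: the progression component is first fitted to
    the control-arm data, drug-effect parameters start at neutral values,
    then all free parameters are refined jointly.
    """
    effect_model = str(effect_model).upper()
    staged, fixed_vals = _staged_init(ds, effect_model, conventions, seed)
    fixed = dict(fixed or {})
    fixed.setdefault("kout_sol", 1.1)
    for k, v in fixed_vals.items():
        fixed.setdefault(k, v)
    model = build_pkpd_model(ds, pk_params, effect_model, fixed=fixed,
                             conventions=conventions, use_unbound=use_unbound,
                             h_dose=h_dose)
    full_init = dict(staged)
    if init:
        full_init.update(init)
    full_init = {k: v for k, v in full_init.items() if k in model.free_names}
    for p in model.free_names:
        if p not in full_init:
            raise ValidationError(f"no initial value for parameter {p!r}")
        lo, hi = model.bounds.get(p, (None, None))
        if lo is not None:
            full_init[p] = min(max(full_init[p], lo * 1.0000001), hi * 0.9999999)
    error = ErrorModel("proportional")
    fit = fit_model(model, error, full_init, n_starts=n_starts, seed=seed,
                    maxiter=maxiter)
    if compute_se:
        standard_errors(fit, model, error)
    return fit
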