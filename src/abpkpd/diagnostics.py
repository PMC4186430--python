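"""Model diagnostics: visual predictive checks, treatment-effect summaries
and the soluble-vs-insoluble reduction regression."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datamodel import (
    Arm,
    Dataset,
    DEFAULT_CONVENTIONS,
    Endpoint,
    UnitConventions,
    ValidationError,
)
from .estimation import PKPDPredictor
from .pk import PKParams
from .pkpd import PDParams, simulate
from .synthetic import NoiseSpec, _draw_noisy


@dataclass
class VPCResult:
    """Per-bin percentiles of simulated observations with the data overlay."""

    binning: str                      # "age" (months) or "time" (hours)
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    observed_x: np.ndarray
    observed_y: np.ndarray
    n_sim: int
    seed: int
    endpoint: Endpoint = Endpoint.sol_ab40

    def __post_init__(self):
        ok = (self.p5 <= self.p50 + 1e-12) & (self.p50 <= self.p95 + 1e-12)
        if not np.all(ok[np.isfinite(self.p50)]):
            raise ValidationError("percentile ordering violated")


def vpc(ds: Dataset, pk: PKParams, pd: PDParams, noise: NoiseSpec,
        n_sim: int = 1000, *, endpoint: Endpoint = Endpoint.sol_ab40,
        binning: str = "age", bin_edges=None, n_bins: int = 10,
        conventions: UnitConventions = DEFAULT_CONVENTIONS) -> VPCResult:
    """Visual predictive check for one Aβ40 endpoint.

    The observed design (animals, dosing histories, sampling times) is
    replicated ``n_sim`` times under the model: predictions are computed
    once from the fixed PK/PD parameters, then residual noise (and, if
    specified, per-animal PK between-subject variability) is redrawn per
    replicate. The 5th/50th/95th percentiles of the simulated observations
    are summarised per bin of termination age (months) or observation time
    (hours).
    """
    endpoint = Endpoint(endpoint)
    meta = ds.animal_index
    obs = [o for o in ds.observations if o.endpoint is endpoint and not o.blq_flag]
    if not obs:
        raise ValidationError(f"no observations for {endpoint}")
    if binning == "age":
        x = np.array([meta[o.animal_id].age_at_start_months
                      + o.time_h / conventions.hours_per_month for o in obs])
    elif binning == "time":
        x = np.array([o.time_h for o in obs])
    else:
        raise ValidationError("binning must be 'age' or 'time'")
    y_obs = np.array([o.value for o in obs])
    rng = np.random.default_rng(noise.seed)
    err = noise.residual.get(endpoint)
    has_bsv = any(v > 0 for v in noise.pk_bsv.values())

    col = 0 if endpoint in (Endpoint.sol_ab40, Endpoint.sol_ab42) else 1

    def _predictions(pk_use: PKParams, per_animal_rng=None) -> np.ndarray:
        if per_animal_rng is None:
            sub = Dataset(animals=list(ds.animals), doses=dict(ds.doses),
                          observations=obs)
            pred = PKPDPredictor(sub, pk_use, conventions)
            return pred.predict(pd)
        out = np.empty(len(obs))
        by_animal: dict[str, list[int]] = {}
        for i, o in enumerate(obs):
            by_animal.setdefault(o.animal_id, []).append(i)
        for aid, idxs in by_animal.items():
            animal = meta[aid]
            pk_i = replace(pk_use, bsv_omegas=noise.pk_bsv).with_bsv(per_animal_rng)
            t_rel = np.array([obs[i].time_h for i in idxs])
            res = simulate(animal, ds.doses_for(aid), pk_i, pd, t_rel,
                           conventions=conventions)
            vals = res.a_sol if col == 0 else res.a_insol
            for i, v in zip(idxs, vals):
                out[i] = v
        return out

    if not has_bsv:
        base_pred = _predictions(pk)
    sims = np.empty((n_sim, len(obs)))
    for r in range(n_sim):
        pred = _predictions(pk, rng) if has_bsv else base_pred
        sims[r] = [_draw_noisy(rng, m, err) for m in pred]

    if bin_edges is None:
        qs = np.linspace(0, 100, n_bins + 1)
        bin_edges = np.unique(np.percentile(x, qs))
    bin_edges = np.asarray(bin_edges, dtype=float)
    k = bin_edges.size - 1
    p5 = np.full(k, np.nan)
    p50 = np.full(k, np.nan)
    p95 = np.full(k, np.nan)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    idx = np.clip(np.searchsorted(bin_edges, x, side="right") - 1, 0, k - 1)
    for b in range(k):
        vals = sims[:, idx == b].ravel()
        if vals.size:
            p5[b], p50[b], p95[b] = np.percentile(vals, [5, 50, 95])
    return VPCResult(binning=binning, bin_edges=bin_edges, bin_centers=centers,
                     p5=p5, p50=p50, p95=p95, observed_x=x, observed_y=y_obs,
                     n_sim=n_sim, seed=noise.seed, endpoint=endpoint)


def plot_vpc(result: VPCResult, ax=None, ylabel: str | None = None):
    """Plot a VPC band with the observed data overlay (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ok = np.isfinite(result.p50)
    ax.fill_between(result.bin_centers[ok], result.p5[ok], result.p95[ok],
                    alpha=0.3, color="grey", label="90% prediction interval")
    ax.plot(result.bin_centers[ok], result.p50[ok], "k-", label="median")
    ax.plot(result.observed_x, result.observed_y, "o", mfc="none", mec="grey",
            ms=4, label="observed")
    ax.set_xlabel("age (months)" if result.binning == "age" else "time (h)")
    ax.set_ylabel(ylabel or f"{result.endpoint.value} (pg/mg)")
    ax.legend(frameon=False, fontsize=8)
    return ax


# ---------------------------------------------------------------------------
# treatment-effect statistics
# ---------------------------------------------------------------------------

@dataclass
class EffectSummary:
    vehicle_mean: float
    vehicle_sem: float
    treated_mean: float
    treated_sem: float
    percent_change: float
    t_statistic: float
    p_value: float
    significant: bool
    n_vehicle: int
    n_treated: int


def effect_summary(vehicle_values, treated_values, *,
                   welch: bool = False, alpha: float = 0.05) -> EffectSummary:
    """Unpaired two-sided t-test of treated vs vehicle with means ± SEM.

    Student's equal-variance test by default; set ``welch=True`` for the
    unequal-variance variant.
    """
    v = np.asarray(vehicle_values, dtype=float)
    t = np.asarray(treated_values, dtype=float)
    if v.size < 2 or t.size < 2:
        raise ValidationError("each arm needs at least 2 values")
    res = stats.ttest_ind(t, v, equal_var=not welch)
    pct = 100.0 * (t.mean() - v.mean()) / v.mean()
    return EffectSummary(
        vehicle_mean=float(v.mean()), vehicle_sem=float(stats.sem(v)),
        treated_mean=float(t.mean()), treated_sem=float(stats.sem(t)),
        percent_change=float(pct), t_statistic=float(res.statistic),
        p_value=float(res.pvalue), significant=bool(res.pvalue < alpha),
        n_vehicle=int(v.size), n_treated=int(t.size),
    )


def arm_values(ds: Dataset, study_id: str, endpoint: Endpoint,
               dose_amount: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(vehicle, treated) observation vectors for one study/endpoint,
    optionally restricted to one daily-dose group."""
    endpoint = Endpoint(endpoint)
    meta = ds.animal_index
    veh, trt = [], []
    for o in ds.observations:
        if o.endpoint is not endpoint or o.blq_flag:
            continue
        a = meta[o.animal_id]
        if a.study_id != study_id:
            continue
        if a.arm is Arm.treated:
            if dose_amount is not None:
                amts = {d.amount for d in ds.doses_for(o.animal_id)}
                if dose_amount not in amts:
                    continue
            trt.append(o.value)
        elif a.arm in (Arm.vehicle, Arm.naive):
            veh.append(o.value)
    return np.asarray(veh), np.asarray(trt)


# ---------------------------------------------------------------------------
# soluble vs insoluble reduction regression (treatment-duration effect)
# ---------------------------------------------------------------------------

@dataclass
class GroupRegression:
    slope: float
    intercept: float
    r_value: float
    n: int
    degenerate: bool = False


def soluble_insoluble_regression(points) -> dict[str, GroupRegression]:
    """Least-squares regression of observed insoluble Aβ40 reduction on the
    model-predicted average soluble reduction, per treatment-duration group.

    ``points`` is an iterable of (avg_soluble_reduction_pct,
    insoluble_reduction_pct, duration_weeks). Durations ≤ 3 weeks form the
    "1-3wk" group, 3–6 weeks the "4-6wk" group; longer durations are
    ignored (matching the exclusion of the non-significant 12-week data).
    A free intercept is used.
    """
    groups: dict[str, list[tuple[float, float]]] = {}
    for sol, insol, weeks in points:
        if weeks <= 3.0:
            key = "1-3wk"
        elif weeks <= 6.0:
            key = "4-6wk"
        else:
            continue
        groups.setdefault(key, []).append((float(sol), float(insol)))
    out: dict[str, GroupRegression] = {}
    for key, pts in groups.items():
        if len(pts) < 2:
            raise ValidationError(f"group {key} needs >= 2 points")
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if np.ptp(xs) < 1e-12:
            out[key] = GroupRegression(math.nan, math.nan, math.nan,
                                       len(pts), degenerate=True)
            continue
        res = stats.linregress(xs, ys)
        out[key] = GroupRegression(float(res.slope), float(res.intercept),
                                   float(res.rvalue), len(pts))
    return out
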