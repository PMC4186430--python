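"""Shared fixtures and independent ODE oracles for the test suite.

The oracles deliberately use a different integration route (scipy adaptive
LSODA on the raw compartmental equations) than the package's closed-form /
compiled-RK4 implementations they are checking.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from abpkpd.datamodel import AnimalRecord, Arm, DoseEvent, Route, Strain
from abpkpd.pk import PKParams, bioavailability, plasma_concentration
from abpkpd.pkpd import PDParams, rhs
from abpkpd.progression import APParams


@pytest.fixture
def pk_params() -> PKParams:
    return PKParams()


@pytest.fixture
def pd_params() -> PDParams:
    return PDParams()


@pytest.fixture
def young_animal() -> AnimalRecord:
    return AnimalRecord("a1", Strain.tg2576, 5.0, "study-x", Arm.treated)


def daily_oral(amount: float, days: int, vehicle: int = 1) -> list[DoseEvent]:
    return [DoseEvent(24.0 * i, amount, Route.oral, vehicle) for i in range(days)]


def pk_ode_oracle(pk: PKParams, doses: list[DoseEvent], t_eval,
                  study_id=None) -> np.ndarray:
    """Plasma concentration by stiff numerical integration of the
    depot/central/peripheral amount equations with dose resets."""
    te = np.asarray(t_eval, dtype=float)
    dose_times = sorted({d.time_h for d in doses})
    segs = dose_times + [max(te.max(), dose_times[-1]) + 1.0]

    def f(t, y):
        a_po, a_sc, c, p = y
        return [
            -pk.ka_po * a_po,
            -pk.ka_sc * a_sc,
            pk.ka_po * a_po + pk.ka_sc * a_sc - (pk.k10 + pk.k12) * c + pk.k21 * p,
            pk.k12 * c - pk.k21 * p,
        ]

    y = np.zeros(4)
    out = np.full(te.shape, np.nan)
    for i, t0 in enumerate(segs[:-1]):
        for d in doses:
            if abs(d.time_h - t0) < 1e-12:
                amt = bioavailability(d.amount, d.route, d.vehicle, pk, study_id) * d.amount
                if d.route is Route.iv:
                    y[2] += amt
                elif d.route is Route.oral:
                    y[0] += amt
                else:
                    y[1] += amt
        t1 = segs[i + 1]
        last = i == len(segs) - 2
        mask = (te >= t0) & ((te >= t0) if last else (te < t1))
        if not last:
            mask = (te >= t0) & (te < t1)
        tev = np.unique(np.concatenate([te[mask], [t1]]))
        sol = solve_ivp(f, (t0, t1), y, method="LSODA", rtol=1e-11, atol=1e-14,
                        t_eval=tev)
        if te[mask].size:
            idx = np.searchsorted(sol.t, te[mask])
            out[mask] = sol.y[2][idx] / pk.v2
        y = sol.y[:, -1]
    out[te < segs[0]] = 0.0
    return out


def pkpd_ode_oracle(animal: AnimalRecord, doses: list[DoseEvent],
                    pk: PKParams, pd: PDParams, t_eval_rel,
                    hours_per_month: float = 730.5) -> np.ndarray:
    """(A_sol, A_insol) trajectories via adaptive LSODA on the reference
    right-hand side, drug forcing from the closed-form plasma curve."""
    start_h = animal.age_at_start_months * hours_per_month
    dabs = [DoseEvent(start_h + d.time_h, d.amount, d.route, d.vehicle)
            for d in doses]

    def f(t, y):
        cb = pk.brain_plasma_ratio * plasma_concentration(
            np.array([t]), dabs, pk, animal.study_id)[0]
        return rhs(t, y, cb, pd)

    t_abs = start_h + np.asarray(t_eval_rel, dtype=float)
    sol = solve_ivp(f, (0.0, float(t_abs.max())),
                    [pd.ap.baseline, pd.baseline_insol],
                    method="LSODA", rtol=1e-9, atol=1e-11,
                    t_eval=t_abs, max_step=4.0)
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.y
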