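"""Integrated turnover model: drug-effect terms, scaling, simulation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from abpkpd.datamodel import AnimalRecord, Arm, DoseEvent, Route, Strain, ValidationError
from abpkpd.pk import ConfigurationError, PKParams
from abpkpd.pkpd import (
    PDParams,
    PDState,
    average_soluble_reduction,
    ic50_of_level,
    inhibition,
    rhs,
    scale_function,
    simulate,
)
from abpkpd.progression import ap_level

from conftest import daily_oral, pkpd_ode_oracle


def _animal(age_months: float, ident="t1") -> AnimalRecord:
    return AnimalRecord(ident, Strain.tg2576, age_months, "sim", Arm.treated)


class TestIC50OfLevel:
    def test_young_baseline_anchor(self, pd_params):
        # at the 57.1 pg/mg baseline the IC50 is ~0.11 μmol/L
        assert ic50_of_level(57.1, 514.0) == pytest.approx(0.111, rel=0.02)

    def test_old_age_anchor(self, pd_params):
        level_25mo = ap_level(25.0, pd_params.ap)
        assert ic50_of_level(level_25mo, 514.0) == pytest.approx(12.0, rel=0.10)

    def test_linear_through_origin(self):
        assert ic50_of_level(0.0, 514.0) == 0.0


class TestInhibition:
    def test_zero_concentration_all_models(self, pd_params):
        model_a = replace(pd_params, effect_model="A")
        model_b = replace(pd_params, effect_model="B", ic50_fixed=0.11)
        for p in (model_a, model_b, pd_params):
            assert inhibition(0.0, 57.1, p) == 0.0

    def test_saturating_inhibition_model_c(self, pd_params):
        assert inhibition(1e9, 57.1, pd_params) == pytest.approx(0.86, rel=1e-6)

    def test_hill_midpoint_model_b(self, pd_params):
        p = replace(pd_params, effect_model="B", ic50_fixed=0.2)
        assert inhibition(0.2, 57.1, p) == pytest.approx(p.imax / 2.0)

    def test_model_c_inhibition_decreases_with_level(self, pd_params):
        assert inhibition(0.5, 57.1, pd_params) > inhibition(0.5, 6000.0, pd_params)

    def test_model_b_requires_ic50(self, pd_params):
        with pytest.raises(ConfigurationError):
            PDParams(effect_model="B")


class TestScaleFunction:
    def test_plateau(self, pd_params):
        assert scale_function(1e9, pd_params) == pytest.approx(6.5, rel=1e-6)

    def test_hill_midpoint(self, pd_params):
        assert scale_function(7610.0, pd_params) == pytest.approx(3.25)

    def test_plateau_consistency_with_insoluble_curve(self, pd_params):
        # α2 × soluble plateau should land near the insoluble plateau
        predicted = pd_params.alpha2 * pd_params.ap.alpha
        assert predicted == pytest.approx(39900.0, rel=0.15)

    def test_monotone_bounded(self, pd_params):
        t = np.linspace(0.0, 30000.0, 500)
        s = scale_function(t, pd_params)
        assert np.all(np.diff(s) >= 0) and np.all(s <= pd_params.alpha2)


class TestRHS:
    def test_drug_free_steady_state(self, pd_params):
        t = 10.0 * 730.5
        a_sol = ap_level(10.0, pd_params.ap)
        d = rhs(t, [a_sol, 100.0], 0.0, pd_params)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_insoluble_decay_half_life(self, pd_params):
        # with production switched off the insoluble pool decays with
        # t1/2 = ln2 / k_out,insol ≈ 28.9 days
        p = replace(pd_params, baseline_insol=1e-300)
        d = rhs(0.0, [0.0, 1000.0], 0.0, p)
        k = -d[1] / 1000.0
        assert math.log(2.0) / k / 24.0 == pytest.approx(28.9, rel=0.01)

    def test_full_inhibition_leaves_pure_loss(self, pd_params):
        p = replace(pd_params, effect_model="B", ic50_fixed=1e-12, imax=1.0)
        a_sol = 50.0
        d = rhs(5.0 * 730.5, [a_sol, 30.0], 1e3, p)
        assert d[0] == pytest.approx(-p.kout_sol * a_sol, rel=1e-6)

    def test_state_validation(self):
        with pytest.raises(ValidationError):
            PDState(-1.0, 0.0)


class TestSimulate:
    def test_drug_free_tracks_progression(self, pk_params, pd_params):
        animal = AnimalRecord("n1", Strain.tg2576, 1.0, "free", Arm.naive)
        t_rel = np.linspace(0.0, 25.0 * 730.5, 60)
        res = simulate(animal, [], pk_params, pd_params, t_rel)
        ages = res.times_h / 730.5
        expected = ap_level(ages, pd_params.ap)
        np.testing.assert_allclose(res.a_sol, expected, rtol=0.01)

    def test_model_b_reduction_age_invariant(self, pk_params, pd_params):
        p = replace(pd_params, effect_model="B", ic50_fixed=0.11)
        reductions = {}
        for age in (5.0, 15.0):
            res = simulate(_animal(age), daily_oral(6.0, 28), pk_params, p,
                           np.array([27.0 * 24.0 + 3.0]))
            reductions[age] = 1.0 - res.a_sol[0] / res.ap_reference[0]
        assert reductions[5.0] == pytest.approx(reductions[15.0], abs=0.02)

    def test_model_c_reduction_declines_with_age(self, pk_params, pd_params):
        reductions = {}
        for age in (5.0, 15.0):
            res = simulate(_animal(age), daily_oral(6.0, 28), pk_params,
                           pd_params, np.array([27.0 * 24.0 + 3.0]))
            reductions[age] = 1.0 - res.a_sol[0] / res.ap_reference[0]
        assert reductions[15.0] < reductions[5.0] - 0.1

    def test_reference_bounds_treated_trajectory(self, pk_params, pd_params):
        res = simulate(_animal(5.0), daily_oral(6.0, 14), pk_params, pd_params,
                       np.linspace(0.0, 15.0 * 24, 200))
        assert np.all(res.ap_reference >= res.a_sol - 1e-9)

    def test_positivity_under_aggressive_dosing(self, pk_params, pd_params):
        doses = daily_oral(70.0, 30)
        res = simulate(_animal(5.0), doses, pk_params, pd_params,
                       np.linspace(0.0, 31.0 * 24, 400))
        assert np.all(res.a_sol >= 0) and np.all(res.a_insol >= 0)

    @pytest.mark.parametrize("model_kwargs", [
        {"effect_model": "C"},
        {"effect_model": "B", "ic50_fixed": 0.11},
        {"effect_model": "A"},
    ])
    def test_engine_matches_adaptive_oracle(self, pk_params, pd_params,
                                            model_kwargs):
        p = replace(pd_params, **model_kwargs)
        doses = daily_oral(6.0, 7)
        t_rel = np.linspace(0.0, 8.0 * 24, 60)
        res = simulate(_animal(5.0), doses, pk_params, p, t_rel)
        oracle = pkpd_ode_oracle(_animal(5.0), doses, pk_params, p, t_rel)
        np.testing.assert_allclose(res.a_sol, oracle[0], rtol=5e-3)
        np.testing.assert_allclose(res.a_insol, oracle[1], rtol=5e-3)


class TestTimescales:
    def test_soluble_step_response_half_life(self, pk_params, pd_params):
        # clamp inhibition at I_max: soluble settles with t1/2 = ln2/1.1 ≈ 38 min
        p = replace(pd_params, effect_model="B", ic50_fixed=1e-9)
        t_rel = np.linspace(0.0, 6.0, 700)
        res = simulate(_animal(5.0), [DoseEvent(0.0, 70.0, Route.oral, 1)],
                       pk_params, p, t_rel)
        start = res.a_sol[0]
        target = res.ap_reference * (1.0 - p.imax)
        # fit exponential decay rate over the first hours of the step
        gap = (res.a_sol - target) / (start - target[0])
        mask = (gap > 0.05) & (gap < 0.9)
        k_fit = np.polyfit(res.times_h[mask] - res.times_h[0],
                           np.log(gap[mask]), 1)[0]
        half_life_min = math.log(2.0) / -k_fit * 60.0
        assert half_life_min == pytest.approx(38.0, rel=0.15)

    def test_insoluble_responds_on_month_scale(self, pk_params, pd_params):
        # in old animals (AP and SCALE at plateau) the insoluble response to
        # a sustained production step grows as 1 − exp(−k_out,insol·t);
        # younger ages violate the quasi-stationary premise of that oracle
        p = replace(pd_params, effect_model="B", ic50_fixed=1e-9)
        weeks = {}
        for days in (7, 28):
            res = simulate(_animal(20.0), daily_oral(6.0, days), pk_params, p,
                           np.array([(days - 1) * 24.0 + 3.0]))
            ref = simulate(_animal(20.0), [], pk_params, p,
                           np.array([(days - 1) * 24.0 + 3.0]))
            weeks[days] = 1.0 - res.a_insol[0] / ref.a_insol[0]
        expected_ratio = (1 - math.exp(-0.001 * 28 * 24)) / (1 - math.exp(-0.001 * 7 * 24))
        assert weeks[28] / weeks[7] == pytest.approx(expected_ratio, rel=0.15)


class TestAverageReduction:
    def test_drug_free_average_is_zero(self, pk_params, pd_params):
        res = simulate(_animal(5.0), [], pk_params, pd_params,
                       np.linspace(0.0, 500.0, 100))
        assert average_soluble_reduction(
            res, (res.times_h[0], res.times_h[-1])) == pytest.approx(0.0, abs=0.01)

    def test_sustained_max_inhibition_approaches_imax(self, pk_params, pd_params):
        p = replace(pd_params, effect_model="B", ic50_fixed=1e-9)
        res = simulate(_animal(5.0), daily_oral(6.0, 30), pk_params, p,
                       np.linspace(24.0, 29.0 * 24, 400))
        avg = average_soluble_reduction(res, (res.times_h[0], res.times_h[-1]))
        assert avg == pytest.approx(86.0, abs=2.0)

    def test_single_dose_average_below_peak(self, pk_params, pd_params):
        res = simulate(_animal(5.0), [DoseEvent(0.0, 70.0, Route.oral, 1)],
                       pk_params, pd_params, np.linspace(0.0, 120.0, 300))
        red = 100.0 * (1.0 - res.a_sol / res.ap_reference)
        avg = average_soluble_reduction(res, (res.times_h[0], res.times_h[-1]))
        assert avg < red.max()

    def test_empty_window_rejected(self, pk_params, pd_params):
        res = simulate(_animal(5.0), [], pk_params, pd_params,
                       np.linspace(0.0, 100.0, 50))
        with pytest.raises(ValidationError):
            average_soluble_reduction(res, (1e9, 2e9))
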