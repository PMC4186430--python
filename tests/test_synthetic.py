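"""Synthetic-data generator: reproducibility, noise calibration, designs."""

import numpy as np
import pytest

from abpkpd.datamodel import Arm, Endpoint, Route, Strain, ValidationError
from abpkpd.estimation import ErrorModel, fit_ap
from abpkpd.pk import PKParams
from abpkpd.pkpd import PDParams, simulate
from abpkpd.progression import DEFAULT_PROGRESSION_PARAMS, ap_level
from abpkpd.synthetic import (
    NoiseSpec,
    StudyDesignSpec,
    generate_cross_sectional,
    generate_study,
    study_catalogue,
)

SOL40 = DEFAULT_PROGRESSION_PARAMS[Endpoint.sol_ab40]


class TestCrossSectional:
    def test_noise_free_equals_progression_curve(self):
        ds = generate_cross_sectional(25, (3.5, 26.0), SOL40, NoiseSpec(seed=1))
        meta = ds.animal_index
        for o in ds.observations:
            age = meta[o.animal_id].age_at_start_months
            assert o.value == pytest.approx(ap_level(age, SOL40))

    def test_same_seed_identical_datasets(self):
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          seed=42)
        d1 = generate_cross_sectional(50, (3.5, 26.0), SOL40, noise)
        d2 = generate_cross_sectional(50, (3.5, 26.0), SOL40, noise)
        assert [o.value for o in d1.observations] == [o.value for o in d2.observations]
        assert d1.metadata["seed"] == 42

    def test_proportional_cv_calibration(self):
        # all animals at one age: the empirical CV must match the nominal 51%
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          seed=7)
        ds = generate_cross_sectional(5000, (3.5, 26.0), SOL40, noise,
                                      ages=np.full(5000, 20.0))
        values = np.array([o.value for o in ds.observations])
        cv = values.std() / values.mean()
        assert 0.45 <= cv <= 0.57
        assert values.mean() == pytest.approx(ap_level(20.0, SOL40), rel=0.03)

    def test_no_negative_values_at_high_cv(self):
        noise = NoiseSpec(residual={Endpoint.insol_ab40: ErrorModel("proportional", 0.83)},
                          seed=3)
        insol = DEFAULT_PROGRESSION_PARAMS[Endpoint.insol_ab40]
        ds = generate_cross_sectional(2000, (3.5, 26.0), insol, noise)
        assert all(o.value >= 0 for o in ds.observations)

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            generate_cross_sectional(10, (5.0, 5.0), SOL40, NoiseSpec(seed=0))

    def test_end_to_end_recovery_contract(self):
        # vehicle-arm age trends, fed to fit_ap, recover the generating curve
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.2)},
                          seed=19)
        ds = generate_cross_sectional(300, (3.5, 26.0), SOL40, noise)
        fit = fit_ap(ds, Endpoint.sol_ab40, n_starts=4, seed=0)
        assert fit.converged
        assert fit.estimates["alpha"] == pytest.approx(SOL40.alpha, rel=0.10)


class TestGenerateStudy:
    def test_serial_sampling_study_layout(self):
        # single 70 μmol/kg dose, 30+30 animals over 5 terminal cohorts
        spec = {s.study_id: s for s in study_catalogue()}["14"]
        ds = generate_study(spec, PKParams(), PDParams(),
                            NoiseSpec.reference(seed=0))
        assert len(ds.animals) == 60
        treated_times = {o.time_h for o in ds.observations
                         if ds.animal_index[o.animal_id].arm is Arm.treated}
        assert len(treated_times) >= 5

    def test_zero_noise_matches_simulation_exactly(self):
        spec = StudyDesignSpec(
            study_id="t", strain=Strain.tg2576, age_at_start_months=5.0,
            n_treated=2, n_vehicle=1, treatment_days=4, daily_doses=[6.0],
            sample_times_post_dose_h=[3.0])
        ds = generate_study(spec, PKParams(), PDParams(), NoiseSpec(seed=0))
        treated = [o for o in ds.observations
                   if ds.animal_index[o.animal_id].arm is Arm.treated
                   and o.endpoint is Endpoint.sol_ab40]
        animal = ds.animal_index[treated[0].animal_id]
        res = simulate(animal, ds.doses_for(animal.animal_id), PKParams(),
                       PDParams(), np.array([treated[0].time_h]))
        assert treated[0].value == pytest.approx(float(res.a_sol[0]), rel=1e-12)

    def test_vehicle_arm_means_follow_progression(self):
        spec = StudyDesignSpec(
            study_id="v", strain=Strain.tg2576, age_at_start_months=5.5,
            n_treated=1, n_vehicle=400, treatment_days=30, daily_doses=[6.0],
            sample_times_post_dose_h=[3.0])
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          seed=5)
        ds = generate_study(spec, PKParams(), PDParams(), noise)
        veh = np.array([o.value for o in ds.observations
                        if ds.animal_index[o.animal_id].arm is Arm.vehicle
                        and o.endpoint is Endpoint.sol_ab40])
        term_age = 5.5 + (29 * 24.0 + 3.0) / 730.5
        expected = ap_level(term_age, PDParams().ap)
        assert veh.mean() == pytest.approx(expected, rel=0.10)

    def test_seed_reproducibility(self):
        spec = {s.study_id: s for s in study_catalogue()}["8"]
        noise = NoiseSpec.reference(seed=21, with_bsv=True)
        d1 = generate_study(spec, PKParams(), PDParams(), noise)
        d2 = generate_study(spec, PKParams(), PDParams(), noise)
        assert [o.value for o in d1.observations] == [o.value for o in d2.observations]

    def test_lloq_censoring_flags(self):
        spec = StudyDesignSpec(
            study_id="q", strain=Strain.tg2576, age_at_start_months=5.0,
            n_treated=6, n_vehicle=0, treatment_days=1, daily_doses=[70.0],
            sample_times_post_dose_h=[3.0])
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          lloq={Endpoint.sol_ab40: 1e9}, seed=0)
        ds = generate_study(spec, PKParams(), PDParams(), noise)
        assert all(o.blq_flag for o in ds.observations
                   if o.endpoint is Endpoint.sol_ab40)


class TestStudyCatalogue:
    def test_has_23_designs(self):
        assert len(study_catalogue()) == 23

    def test_study_9_duration(self):
        spec = {s.study_id: s for s in study_catalogue()}["9"]
        assert spec.treatment_days == 94

    def test_doses_and_routes_valid(self):
        for spec in study_catalogue():
            assert all(d > 0 for d in spec.daily_doses)
            assert spec.route in (Route.oral, Route.sc, Route.iv)
            assert all(t >= 0 for t in spec.sample_times_post_dose_h)

    def test_study_8_transcription(self):
        spec = {s.study_id: s for s in study_catalogue()}["8"]
        assert spec.n_treated == 30 and spec.n_vehicle == 15
        assert spec.treatment_days == 30
        assert spec.daily_doses == [0.5, 6.0]
        assert spec.age_at_start_months == pytest.approx(24 * 7 / 30.4375)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            StudyDesignSpec(study_id="x", strain=Strain.tg2576,
                            age_at_start_months=5.0, n_treated=0, n_vehicle=0,
                            treatment_days=1, daily_doses=[6.0])
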