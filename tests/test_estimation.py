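"""Pooled-likelihood machinery: OFV, fits, standard errors, model ranking."""

import math

import numpy as np
import pytest

from abpkpd.datamodel import (
    AnimalRecord,
    Arm,
    Dataset,
    Endpoint,
    Observation,
    Strain,
    ValidationError,
)
from abpkpd.estimation import (
    ErrorModel,
    ModelSpec,
    compare_models,
    fit_ap,
    fit_model,
    negloglik,
    standard_errors,
)
from abpkpd.progression import APParams, DEFAULT_PROGRESSION_PARAMS, ap_level
from abpkpd.synthetic import NoiseSpec, generate_cross_sectional

SOL40 = DEFAULT_PROGRESSION_PARAMS[Endpoint.sol_ab40]


def _linear_model(x, y, sd=None, fixed=None):
    """y = a + b·x with additive error — closed-form oracle territory."""

    def predict(params):
        return params["a"] + params["b"] * x

    return ModelSpec(
        name="linear", predict=predict, obs_values=y,
        obs_endpoints=[Endpoint.sol_ab40] * len(y),
        param_names=["a", "b"],
        transforms={"a": "identity", "b": "identity"},
        bounds={}, fixed=fixed or {},
    )


class TestNegloglik:
    def test_matches_hand_written_gaussian_sum(self):
        # 5-point fixture: compare against an explicit per-point sum
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.2, 2.9, 5.1, 7.4, 8.6])
        model = _linear_model(x, y)
        params = {"a": 1.0, "b": 2.0}
        sd = 0.7
        f = params["a"] + params["b"] * x
        by_hand = sum(
            math.log(2 * math.pi * sd**2) + (yi - fi) ** 2 / sd**2
            for yi, fi in zip(y, f)
        )
        ofv = negloglik(params, model, ErrorModel("additive", sd))
        assert ofv == pytest.approx(by_hand, rel=1e-12)

    def test_proportional_matches_hand_sum(self):
        y = np.array([10.0, 20.0, 40.0])
        model = _linear_model(np.zeros(3), y)
        params = {"a": 25.0, "b": 0.0}
        cv = 0.5
        by_hand = sum(
            math.log(2 * math.pi * (cv * 25.0) ** 2) + (yi - 25.0) ** 2 / (cv * 25.0) ** 2
            for yi in y
        )
        assert negloglik(params, model, ErrorModel("proportional", cv)) == \
            pytest.approx(by_hand, rel=1e-12)

    def test_perturbation_increases_ofv_at_noise_free_optimum(self):
        ages = np.linspace(3.5, 26.0, 40)
        noise = NoiseSpec(seed=0)  # no residual entries -> noise-free
        ds = generate_cross_sectional(40, (3.5, 26.0), SOL40, noise, ages=ages)
        from abpkpd.estimation import build_ap_model
        model = build_ap_model(ds, Endpoint.sol_ab40)
        truth = {"alpha": SOL40.alpha, "ec_i": SOL40.ec_i, "p": SOL40.p,
                 "baseline": SOL40.baseline}
        err = ErrorModel("additive", 1.0)
        base = negloglik(truth, model, err)
        for name in truth:
            bumped = dict(truth)
            bumped[name] *= 1.05
            assert negloglik(bumped, model, err) > base


class TestFitAP:
    def test_noise_free_recovery(self):
        # a small fixed additive sd keeps the noise-free likelihood bounded
        ds = generate_cross_sectional(60, (3.5, 26.0), SOL40, NoiseSpec(seed=3))
        fit = fit_ap(ds, Endpoint.sol_ab40, n_starts=4, seed=0,
                     error=ErrorModel("additive", 1.0))
        assert fit.converged
        for name, truth in [("alpha", 6640.0), ("ec_i", 20.0), ("p", 6.4),
                            ("baseline", 48.0)]:
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_ofv_trace_non_increasing(self):
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          seed=11)
        ds = generate_cross_sectional(150, (3.5, 26.0), SOL40, noise)
        fit = fit_ap(ds, Endpoint.sol_ab40, n_starts=1, seed=0)
        assert len(fit.trace) > 2
        assert all(b <= a + 1e-6 * max(1.0, abs(a))
                   for a, b in zip(fit.trace, fit.trace[1:]))

    def test_same_seed_reproduces_fit(self):
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.51)},
                          seed=5)
        ds = generate_cross_sectional(100, (3.5, 26.0), SOL40, noise)
        f1 = fit_ap(ds, Endpoint.sol_ab40, n_starts=3, seed=7)
        f2 = fit_ap(ds, Endpoint.sol_ab40, n_starts=3, seed=7)
        assert f1.estimates == f2.estimates and f1.ofv == f2.ofv

    def test_single_age_dataset_rejected(self):
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.3)},
                          seed=0)
        ds = generate_cross_sectional(20, (3.5, 26.0), SOL40, noise,
                                      ages=np.full(20, 6.0))
        with pytest.raises(ValidationError, match="distinct termination ages"):
            fit_ap(ds, Endpoint.sol_ab40)

    def test_young_only_data_flags_plateau_unidentifiable(self):
        noise = NoiseSpec(residual={Endpoint.sol_ab40: ErrorModel("proportional", 0.3)},
                          seed=2)
        ds = generate_cross_sectional(120, (3.5, 9.5), SOL40, noise)
        from abpkpd.estimation import build_ap_model
        fit = fit_ap(ds, Endpoint.sol_ab40, n_starts=4, seed=0)
        model = build_ap_model(ds, Endpoint.sol_ab40)
        ses = standard_errors(fit, model, ErrorModel("proportional"))
        alpha_uncertain = (
            not fit.extra.get("se_available", False)
            or not math.isfinite(ses["alpha"])
            or ses["alpha"] / fit.estimates["alpha"] > 0.5
            or fit.extra["bound_hit"]["alpha"]
        )
        assert alpha_uncertain


class TestStandardErrors:
    def _fit_linear(self, n, seed=0, sd=0.5):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.0, 10.0, n)
        y = 1.5 + 0.8 * x + rng.normal(0.0, sd, size=n)
        model = _linear_model(x, y)
        fit = fit_model(model, ErrorModel("additive", sd),
                        {"a": 1.0, "b": 1.0})
        ses = standard_errors(fit, model, ErrorModel("additive", sd))
        return x, y, fit, ses

    def test_matches_closed_form_regression_se(self):
        x, y, fit, ses = self._fit_linear(30)
        X = np.column_stack([np.ones_like(x), x])
        cov = 0.5**2 * np.linalg.inv(X.T @ X)
        assert ses["a"] == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-3)
        assert ses["b"] == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-3)

    def test_se_shrinks_with_sqrt_n(self):
        *_, ses_n = self._fit_linear(50)
        *_, ses_2n = self._fit_linear(200)
        assert ses_2n["b"] / ses_n["b"] == pytest.approx(0.5, rel=0.2)

    def test_fixed_parameter_has_no_se(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 25)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.3, 25)
        model = _linear_model(x, y, fixed={"a": 1.5})
        fit = fit_model(model, ErrorModel("additive", 0.3), {"b": 1.0})
        ses = standard_errors(fit, model, ErrorModel("additive", 0.3))
        assert "a" not in ses and "b" in ses


class TestCompareModels:
    def _two_fits(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 30)
        y = 2.0 + 1.0 * x + rng.normal(0, 0.4, 30)
        m = _linear_model(x, y)
        f1 = fit_model(m, ErrorModel("additive", 0.4), {"a": 1.0, "b": 1.0})
        f2 = fit_model(m, ErrorModel("additive", 0.4), {"a": 1.0, "b": 1.0})
        return f1, f2

    def test_identical_fits_tie(self):
        f1, f2 = self._two_fits()
        ranking = compare_models([f1, f2])
        assert ranking[0]["delta_ofv"] == 0.0
        assert ranking[1]["delta_ofv"] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_datasets_rejected(self):
        f1, _ = self._two_fits()
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 30)
        y = 2.0 + 1.0 * x + rng.normal(0, 0.4, 30)
        other = fit_model(_linear_model(x, y), ErrorModel("additive", 0.4),
                          {"a": 1.0, "b": 1.0})
        with pytest.raises(ValidationError):
            compare_models([f1, other])

    def test_unused_extra_parameter_changes_little(self):
        # nested comparison: fixing the intercept at its true value (the
        # generating model) vs freeing it should move the OFV only slightly
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 60)
        y = 0.8 * x + rng.normal(0, 0.3, 60)
        full = fit_model(_linear_model(x, y), ErrorModel("additive", 0.3),
                         {"a": 0.1, "b": 1.0})
        reduced = fit_model(_linear_model(x, y, fixed={"a": 0.0}),
                            ErrorModel("additive", 0.3), {"b": 1.0})
        assert abs(full.ofv - reduced.ofv) < 3.84
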