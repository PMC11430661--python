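"""Pinball loss, brute-force oracle, curve fitting and the sklearn surface."""

import numpy as np
import pytest

from flipnorms.growth import LogisticParams, logistic_eval
from flipnorms.quantile import (
    CohortRecord,
    FitDataError,
    LogisticQuantileRegressor,
    PercentileGrowthModel,
    brute_force_fit,
    fit_all_percentiles,
    fit_quantile_curve,
    pinball_loss,
)


def records_on_curve(params, ages, child_prefix="c"):
    return [CohortRecord(f"{child_prefix}{i}", float(a),
                         float(np.clip(logistic_eval(params, a), 0, 64)))
            for i, a in enumerate(ages)]


class TestPinballLoss:
    @pytest.mark.parametrize("residuals,tau,expected", [
        ([0, 0, 0], 0.5, 0.0),
        ([2, -1], 0.9, 1.9),
        ([1, -1], 0.5, 1.0),
        ([-3], 0.1, 2.7),
    ])
    def test_check_loss_definition(self, residuals, tau, expected):
        assert pinball_loss(residuals, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.2, 1.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            pinball_loss([1.0], tau)


class TestBruteForceOracle:
    def test_exact_member_of_grid_wins_with_zero_loss(self):
        true = LogisticParams(2.0, 60.0, 0.12, 18.0)
        recs = records_on_curve(true, np.linspace(2, 70, 80))
        grid = ([0.0, 2.0, 5.0], [55.0, 60.0], [0.08, 0.12], [15.0, 18.0])
        params, loss = brute_force_fit(recs, 0.5, grid)
        assert params == true
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_single_point_grid(self):
        recs = records_on_curve(LogisticParams(0, 50, 0.1, 20), [5, 30, 60])
        params, loss = brute_force_fit(recs, 0.5, ([1.0], [40.0], [0.2], [25.0]))
        assert (params.a1, params.a2, params.a3, params.a4) == (1.0, 40.0, 0.2, 25.0)

    def test_oversized_grid_rejected(self):
        g = list(range(200))
        with pytest.raises(ValueError):
            brute_force_fit([], 0.5, (g, g, g, [1] * 200))

    def test_optimiser_never_beaten_by_grid(self, rng):
        """Oracle inequality on random small instances: the continuous
        optimiser's loss is <= the best loss on a coarse grid."""
        for trial in range(25):
            true = LogisticParams(
                float(rng.uniform(-5, 8)), float(rng.uniform(45, 64)),
                float(rng.uniform(0.05, 0.3)), float(rng.uniform(10, 30)))
            ages = rng.uniform(2, 70, size=60)
            noise = rng.normal(0, 2, size=60)
            recs = [CohortRecord(f"r{i}", float(a),
                                 float(np.clip(logistic_eval(true, a) + e, 0, 64)))
                    for i, (a, e) in enumerate(zip(ages, noise))]
            grid = (np.linspace(-10, 10, 5), np.linspace(40, 64, 5),
                    np.linspace(0.05, 0.35, 5), np.linspace(5, 35, 5))
            _, grid_loss = brute_force_fit(recs, 0.5, grid)
            fit = fit_quantile_curve(recs, tau=0.5, seed=trial, n_starts=6)
            assert fit.loss <= grid_loss + 1e-9


class TestFitQuantileCurve:
    def test_noiseless_interpolation_recovers_curve(self):
        true = LogisticParams(3.0, 58.0, 0.15, 17.0)
        recs = records_on_curve(true, np.linspace(4, 70, 120))
        fit = fit_quantile_curve(recs, tau=0.5, seed=0)
        assert fit.loss == pytest.approx(0.0, abs=1e-3)
        assert fit.params.a2 == pytest.approx(true.a2, abs=0.2)
        assert fit.params.a4 == pytest.approx(true.a4, abs=0.5)

    def test_constant_age_median_limit(self):
        """At a single age (plus a token far spread to satisfy the span
        precondition) the tau=0.5 fit passes through the sample median."""
        scores = [10.0, 12.0, 14.0, 20.0, 30.0]
        recs = [CohortRecord(f"c{i}", 24.0, s) for i, s in enumerate(scores * 4)]
        recs += [CohortRecord("far0", 60.0, 55.0), CohortRecord("far1", 60.0, 56.0)]
        fit = fit_quantile_curve(recs, tau=0.5, seed=0)
        fitted_at_24 = logistic_eval(fit.params, 24.0)
        assert fitted_at_24 == pytest.approx(14.0, abs=0.3)

    def test_determinism(self):
        true = LogisticParams(0.0, 55.0, 0.1, 20.0)
        rng = np.random.default_rng(3)
        recs = [CohortRecord(f"c{i}", float(a),
                             float(np.clip(logistic_eval(true, a) + rng.normal(0, 3), 0, 64)))
                for i, a in enumerate(rng.uniform(2, 70, 100))]
        f1 = fit_quantile_curve(recs, tau=0.5, seed=11)
        f2 = fit_quantile_curve(recs, tau=0.5, seed=11)
        assert f1.params == f2.params
        assert f1.loss == f2.loss

    def test_loss_invariant_to_record_permutation_and_ids(self):
        true = LogisticParams(0.0, 55.0, 0.1, 20.0)
        rng = np.random.default_rng(5)
        recs = [CohortRecord(f"c{i}", float(a),
                             float(np.clip(logistic_eval(true, a) + rng.normal(0, 2), 0, 64)))
                for i, a in enumerate(rng.uniform(2, 70, 80))]
        relabelled = [CohortRecord(f"z{i}", r.age, r.score)
                      for i, r in enumerate(reversed(recs))]
        f1 = fit_quantile_curve(recs, tau=0.5, seed=2)
        f2 = fit_quantile_curve(relabelled, tau=0.5, seed=2)
        assert f1.loss == pytest.approx(f2.loss, abs=1e-9)

    def test_too_few_records(self):
        recs = records_on_curve(LogisticParams(0, 55, 0.1, 20), np.linspace(5, 60, 10))
        with pytest.raises(FitDataError):
            fit_quantile_curve(recs, tau=0.5)

    def test_degenerate_age_span(self):
        recs = [CohortRecord(f"c{i}", 24.0 + 0.01 * i, 20.0) for i in range(30)]
        with pytest.raises(FitDataError):
            fit_quantile_curve(recs, tau=0.5)


class TestFitAllPercentiles:
    def test_single_level_subset(self):
        true = LogisticParams(3.0, 58.0, 0.15, 17.0)
        recs = records_on_curve(true, np.linspace(4, 70, 60))
        table, results, non_crossing, failures = fit_all_percentiles(
            recs, taus=[0.5], n_starts=4)
        assert list(table.entries) == [0.5]
        assert not failures
        assert non_crossing["ok"]

    def test_empty_tau_list_rejected(self):
        with pytest.raises(ValueError):
            fit_all_percentiles([], taus=[])


class TestSklearnSurface:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone
        est = LogisticQuantileRegressor(tau=0.84, n_starts=4, random_state=7)
        cloned = clone(est)
        assert cloned.get_params()["tau"] == 0.84
        cloned.set_params(tau=0.16)
        assert cloned.tau == 0.16

    def test_fit_predict_roundtrip(self):
        true = LogisticParams(3.0, 58.0, 0.15, 17.0)
        ages = np.linspace(4, 70, 100)
        y = np.clip(logistic_eval(true, ages), 0, 64)
        est = LogisticQuantileRegressor(tau=0.5, n_starts=4).fit(ages[:, None], y)
        pred = est.predict(ages[:, None])
        assert np.max(np.abs(pred - y)) < 0.1
        assert est.params_.a2 == pytest.approx(58.0, abs=0.3)

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            LogisticQuantileRegressor().predict([[24.0]])

    def test_family_model_predict_shape(self):
        true = LogisticParams(3.0, 58.0, 0.15, 17.0)
        ages = np.linspace(4, 70, 80)
        y = np.clip(logistic_eval(true, ages), 0, 64)
        model = PercentileGrowthModel(taus=(0.16, 0.5, 0.84), n_starts=3).fit(
            ages[:, None], y)
        out = model.predict([[12.0], [24.0]])
        assert out.shape == (2, 3)
        assert model.non_crossing_["ok"] in (True, False)
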