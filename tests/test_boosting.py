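"""Boosting loop: line search, GBMCI/GBMCOX training, CV, serialization."""

import json
import math

import numpy as np
import pytest

from ciboost.boosting import (
    SurvivalGradientBoosting,
    coxph_negative_gradient,
    fit_gbmci,
    fit_gbmcox,
    line_search_rho,
    select_stages_cv,
)
from ciboost.concordance import concordance_index, smoothed_ci
from ciboost.data import SurvivalDataset, comparable_pairs
from ciboost.simulate import SimulationConfig, simulate_nonlinear, simulate_ph

from conftest import make_instance


def dense_grid_max(scores, preds, data, alpha, npoints=10_000, rho_max=100.0):
    best = -np.inf
    for rho in np.linspace(0.0, rho_max, npoints):
        best = max(best, smoothed_ci(scores + rho * preds, data, alpha))
    return best


@pytest.fixture(scope="module")
def small_nonlinear():
    return simulate_nonlinear(SimulationConfig(n=150, p=3, risk_fn="nonlinear", seed=4))[0]


@pytest.fixture(scope="module")
def small_linear():
    return simulate_ph(SimulationConfig(n=150, p=2, beta=[1.0, -0.5], seed=9))[0]


class TestLineSearch:
    def test_zero_preds_returns_zero(self, rng):
        d = make_instance(rng, 20)
        s = rng.standard_normal(20)
        rho, val = line_search_rho(s, np.zeros(20), d)
        assert rho == 0.0
        assert val == pytest.approx(smoothed_ci(s, d, 1.0))

    def test_monotone_objective_hits_boundary(self):
        d = SurvivalDataset([1.0, 2.0], [1, 1], np.zeros((2, 1)))
        rho, val = line_search_rho([1.0, 0.0], [-1.0, 1.0], d, alpha=1.0)
        # SCI(rho) = sigmoid(2 rho - 1) is increasing: optimum at the bound
        assert rho == pytest.approx(100.0)
        assert val == pytest.approx(1.0 / (1.0 + math.exp(1 - 200)))

    def test_never_below_current_sci(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = make_instance(r, 30)
            s, f = r.standard_normal(30), r.standard_normal(30)
            _, val = line_search_rho(s, f, d)
            assert val >= smoothed_ci(s, d, 1.0) - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_dense_grid(self, seed):
        rng = np.random.default_rng(seed)
        d = make_instance(rng, 40)
        s = rng.standard_normal(40)
        f = 0.3 * rng.standard_normal(40)
        _, val = line_search_rho(s, f, d)
        assert val >= dense_grid_max(s, f, d, 1.0, npoints=2000) - 1e-9

    def test_rho_range_must_start_at_zero(self, rng):
        d = make_instance(rng, 10)
        with pytest.raises(ValueError, match="start at 0"):
            line_search_rho(np.zeros(10), np.ones(10), d, rho_range=(1.0, 10.0))


class TestGbmci:
    def test_zero_stages_equals_cox_initialization(self, small_linear):
        from ciboost.coxph import fit_coxph

        model = fit_gbmci(small_linear, n_estimators=0, cv=0, random_state=1)
        cox = fit_coxph(small_linear)
        np.testing.assert_allclose(
            model.predict(small_linear.X), cox.predict(small_linear.X), rtol=1e-10
        )

    def test_training_sci_non_decreasing_full_bag(self, small_nonlinear):
        model = fit_gbmci(
            small_nonlinear, n_estimators=40, max_depth=2, cv=0,
            subsample=1.0, random_state=3,
        )
        assert np.all(np.diff(model.training_log_) >= -1e-12)

    def test_additive_stage_decomposition(self, small_nonlinear):
        model = fit_gbmci(
            small_nonlinear, n_estimators=8, max_depth=2, cv=0, random_state=3
        )
        X = small_nonlinear.X
        for m in range(1, len(model.stages_) + 1):
            rho, tree = model.stages_[m - 1]
            delta = model.predict(X, n_stages=m) - model.predict(X, n_stages=m - 1)
            np.testing.assert_allclose(
                delta, model.learning_rate_ * rho * tree.predict(X), atol=1e-10
            )

    def test_final_scores_bookkeeping(self, small_nonlinear):
        model = fit_gbmci(
            small_nonlinear, n_estimators=15, max_depth=2, cv=0, random_state=3
        )
        replay = model.predict(small_nonlinear.X, n_stages=len(model.stages_))
        np.testing.assert_allclose(replay, model.final_train_scores_, atol=1e-10)

    def test_subsampled_fit_runs_and_predicts(self, small_nonlinear):
        model = fit_gbmci(
            small_nonlinear, n_estimators=10, max_depth=2, cv=0,
            subsample=0.5, random_state=7,
        )
        assert len(model.stages_) == 10
        assert np.all(np.isfinite(model.predict(small_nonlinear.X)))

    def test_does_not_destroy_correct_linear_fit(self):
        # starts from the Cox solution, so held-out CI must stay close to it
        train, _ = simulate_ph(SimulationConfig(n=300, p=2, beta=[1.0, -0.5], seed=21))
        test, _ = simulate_ph(SimulationConfig(n=300, p=2, beta=[1.0, -0.5], seed=22))
        from ciboost.coxph import fit_coxph

        cox_ci = concordance_index(fit_coxph(train).predict(test.X), test)
        model = fit_gbmci(train, n_estimators=30, max_depth=2, cv=0, random_state=5)
        boost_ci = concordance_index(model.predict(test.X), test)
        assert boost_ci >= cox_ci - 0.02

    def test_shrinkage_damping_halves_stage_changes(self, small_nonlinear):
        import copy

        model = fit_gbmci(
            small_nonlinear, n_estimators=6, max_depth=2, cv=0,
            learning_rate=0.5, random_state=3,
        )
        halved = copy.deepcopy(model)
        halved.learning_rate_ = model.learning_rate_ / 2
        X = small_nonlinear.X
        for m in range(1, len(model.stages_) + 1):
            full = model.predict(X, n_stages=m) - model.predict(X, n_stages=m - 1)
            half = halved.predict(X, n_stages=m) - halved.predict(X, n_stages=m - 1)
            np.testing.assert_allclose(half, full / 2, atol=1e-14)

    def test_zero_comparable_pairs_error(self):
        d = SurvivalDataset([1.0, 1.0, 1.0], [1, 1, 1], np.eye(3))
        with pytest.raises(ValueError, match="comparable"):
            fit_gbmci(d, n_estimators=3, cv=0)


class TestGbmcox:
    @pytest.mark.parametrize("seed", range(10))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        d = make_instance(rng, n, censor_frac=0.3)
        F = rng.standard_normal(n)

        def objective(scores):
            val = 0.0
            for i in range(n):
                if d.status[i] == 1:
                    denom = sum(
                        math.exp(scores[j]) for j in range(n) if d.time[j] >= d.time[i]
                    )
                    val -= scores[i] - math.log(denom)
            return val

        g = coxph_negative_gradient(F, d.time, d.status)
        h = 1e-6
        fd = np.empty(n)
        for i in range(n):
            up, dn = F.copy(), F.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = -(objective(up) - objective(dn)) / (2 * h)
        assert np.linalg.norm(g - fd) / max(np.linalg.norm(fd), 1e-30) < 1e-6

    def test_all_censored_error(self):
        d = SurvivalDataset([1.0, 2.0, 3.0], [0, 0, 0], np.eye(3))
        with pytest.raises(ValueError, match="events|comparable"):
            fit_gbmcox(d, n_estimators=3, cv=0)

    def test_training_objective_decreases(self, small_linear):
        model = fit_gbmcox(
            small_linear, n_estimators=100, max_depth=2, cv=0,
            learning_rate=0.05, random_state=2,
        )
        log = model.training_log_
        assert log[-1] < log[0]

    def test_prediction_orientation_matches_survival(self, small_linear):
        # longer-surviving subjects should get larger scores
        model = fit_gbmcox(
            small_linear, n_estimators=150, max_depth=2, cv=0,
            learning_rate=0.05, random_state=2,
        )
        ci = concordance_index(model.predict(small_linear.X), small_linear)
        assert ci > 0.6


class TestCvSelection:
    def test_single_candidate(self, small_nonlinear):
        best_m, curve = select_stages_cv(
            small_nonlinear, objective="sci", n_estimators=1, max_depth=2,
            cv=3, random_state=1,
        )
        assert best_m == 1 and curve.shape == (1,)

    def test_selected_stages_within_range(self, small_nonlinear):
        model = fit_gbmci(
            small_nonlinear, n_estimators=12, max_depth=2, cv=3, random_state=6
        )
        assert 1 <= model.selected_stages_ <= len(model.stages_)
        assert model.cv_curve_.shape == (12,)

    def test_fold_refit_reproduces_stored_curve(self, small_nonlinear):
        """Refitting a fold from its seed reproduces the stored CV entries."""
        from sklearn.model_selection import KFold

        from ciboost.boosting import _CV_FOLD_KEY
        from ciboost.data import SurvivalDataset as SD

        seed = 6
        est = SurvivalGradientBoosting(
            objective="sci", n_estimators=10, max_depth=2, cv=3, random_state=seed
        )
        est.fit(small_nonlinear.X, small_nonlinear.y)
        kf = KFold(n_splits=3, shuffle=True, random_state=seed % (2**32 - 1))
        tr, va = next(iter(kf.split(small_nonlinear.X)))
        fold = small_nonlinear.subset(tr)
        rng = np.random.default_rng(np.random.SeedSequence([seed, _CV_FOLD_KEY, 0]))
        loop = est._fit_loop(
            fold, rng, X_val=small_nonlinear.X[va],
            y_val=(small_nonlinear.time[va], small_nonlinear.status[va]),
        )
        np.testing.assert_array_equal(loop["val_curve"], est.cv_fold_curves_[0])

    def test_cv_ties_take_smallest_m(self):
        curve = np.array([0.6, 0.7, 0.7, 0.65])
        assert int(np.argmax(curve)) + 1 == 2  # documents the argmax convention


class TestDeterminismAndSerialization:
    def test_identical_seeds_identical_models(self, small_nonlinear):
        kwargs = dict(n_estimators=8, max_depth=2, cv=2, subsample=0.7, random_state=42)
        m1 = fit_gbmci(small_nonlinear, **kwargs)
        m2 = fit_gbmci(small_nonlinear, **kwargs)
        assert [r for r, _ in m1.stages_] == [r for r, _ in m2.stages_]
        np.testing.assert_array_equal(m1.training_log_, m2.training_log_)
        np.testing.assert_array_equal(
            m1.predict(small_nonlinear.X), m2.predict(small_nonlinear.X)
        )
        assert m1.selected_stages_ == m2.selected_stages_

    def test_json_round_trip_predicts_identically(self, small_nonlinear, tmp_path):
        from ciboost.serialize import load_model, save_model

        model = fit_gbmci(
            small_nonlinear, n_estimators=6, max_depth=2, cv=0, random_state=11
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        np.testing.assert_array_equal(
            model.predict(small_nonlinear.X), clone.predict(small_nonlinear.X)
        )
        # the document is valid JSON with a versioned schema
        doc = json.loads(path.read_text())
        assert doc["schema_version"] == 1
        assert len(doc["stages"]) == 6

    def test_round_trip_preserves_additivity(self, small_linear, tmp_path):
        from ciboost.serialize import load_model, save_model

        model = fit_gbmcox(
            small_linear, n_estimators=5, max_depth=2, cv=0,
            learning_rate=0.1, random_state=3,
        )
        save_model(model, tmp_path / "m.json")
        clone = load_model(tmp_path / "m.json")
        X = small_linear.X
        for m in range(1, 6):
            rho, tree = clone.stages_[m - 1]
            delta = clone.predict(X, n_stages=m) - clone.predict(X, n_stages=m - 1)
            np.testing.assert_allclose(
                delta, -clone.learning_rate_ * rho * tree.predict(X), atol=1e-12
            )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"objective": "weibull"},
            {"alpha": 0.0},
            {"subsample": 0.0},
            {"subsample": 1.5},
            {"learning_rate": 0.0},
            {"n_estimators": -1},
            {"rho_max": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs, small_linear):
        with pytest.raises(ValueError):
            fit_gbmci(small_linear, cv=0, **kwargs)
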