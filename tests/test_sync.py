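"""Regression metrics, splits, model comparison and the sync matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from eyesync import (RegressionSpec, default_specs, evaluate_models,
                     fit_sync, mae, mse, r2_score, select_best_model,
                     split_windows)


class TestMetrics:
    def test_hand_worked_example(self):
        y_true = np.array([1.0, 2.0, 3.0])
        y_pred = np.array([1.0, 2.0, 4.0])
        assert mae(y_true, y_pred) == pytest.approx(1 / 3)
        assert mse(y_true, y_pred) == pytest.approx(1 / 3)
        assert r2_score(y_true, y_pred) == pytest.approx(0.5)

    def test_identity_prediction(self, rng):
        y = rng.standard_normal(50)
        assert r2_score(y, y) == 1.0
        assert mae(y, y) == 0.0
        assert mse(y, y) == 0.0

    def test_mean_prediction_scores_zero(self, rng):
        y = rng.standard_normal(50)
        pred = np.full_like(y, y.mean())
        assert r2_score(y, pred) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_vectors(self, rng):
        for _ in range(200):
            n = rng.integers(2, 30)
            y = rng.standard_normal(n)
            p = rng.standard_normal(n)
            assert mae(y, p) == pytest.approx(
                skm.mean_absolute_error(y, p), abs=1e-12)
            assert mse(y, p) == pytest.approx(
                skm.mean_squared_error(y, p), abs=1e-12)
            assert r2_score(y, p) == pytest.approx(
                skm.r2_score(y, p), abs=1e-12)

    def test_zero_variance_target_undefined(self):
        with pytest.raises(ZeroDivisionError):
            r2_score(np.ones(10), np.zeros(10))


class TestSplitWindows:
    @pytest.mark.parametrize("n,expected", [(121, (84, 37)), (10, (7, 3)),
                                            (100, (70, 30))])
    def test_seven_three_arithmetic(self, n, expected):
        train, test = split_windows(n)
        assert (len(train), len(test)) == expected

    def test_chronological_order(self):
        train, test = split_windows(20)
        assert train.max() < test.min()

    def test_random_mode_deterministic(self):
        a = split_windows(50, mode="random", seed=9)
        b = split_windows(50, mode="random", seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=10, max_value=500),
           st.integers(min_value=0, max_value=10))
    def test_disjoint_and_exhaustive(self, n, seed):
        train, test = split_windows(n, mode="random", seed=seed)
        combined = np.sort(np.concatenate([train, test]))
        np.testing.assert_array_equal(combined, np.arange(n))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            split_windows(9)


class TestFitSync:
    def test_identity_regression_perfect(self, rng):
        x = rng.standard_normal(100)
        res = fit_sync(x, x, RegressionSpec(model="linear"))
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.mae == pytest.approx(0.0, abs=1e-9)
        assert res.n_train == 70 and res.n_test == 30

    def test_zero_variance_test_target_flagged(self):
        x = np.arange(20.0)
        y = np.concatenate([np.arange(14.0), np.ones(6)])
        res = fit_sync(x, y, RegressionSpec(model="linear"))
        assert res.undefined and np.isnan(res.r2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_sync(np.zeros(10), np.zeros(11), RegressionSpec())

    def test_hyperparameters_match_printed_settings(self):
        specs = default_specs()
        gbr = specs["gbr"].make_estimator()
        assert (gbr.n_estimators, gbr.learning_rate, gbr.max_depth,
                gbr.subsample) == (100, 0.1, 3, 1.0)
        en = specs["elastic_net"].make_estimator()
        assert (en.alpha, en.l1_ratio) == (1.0, 0.5)
        svr = specs["svr"].make_estimator()
        assert (svr.kernel, svr.C, svr.epsilon, svr.gamma) == (
            "rbf", 1.0, 0.1, "auto")

    def test_gbr_deterministic_under_seed(self, rng):
        x = rng.standard_normal(60)
        y = x + 0.1 * rng.standard_normal(60)
        spec = RegressionSpec(model="gbr", seed=3)
        assert fit_sync(x, y, spec).r2 == fit_sync(x, y, spec).r2


class TestEvaluateModels:
    def test_table_shape(self, rng):
        x = rng.standard_normal(60)
        y = x + 0.2 * rng.standard_normal(60)
        table = evaluate_models(x, y, n_repeats=2)
        assert list(table.columns) == ["model", "ev", "mae", "mse",
                                       "r2_score"]
        assert len(table) == 5

    def test_linear_coupling_low_noise(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + 0.02 * rng.standard_normal(200)
        table = evaluate_models(x, y, n_repeats=3).set_index("model")
        assert table.loc["linear", "r2_score"] >= 0.9

    def test_needs_two_specs(self, rng):
        with pytest.raises(ValueError):
            evaluate_models(rng.standard_normal(20), rng.standard_normal(20),
                            specs={"gbr": RegressionSpec(model="gbr")})


class TestSelectBestModel:
    def test_max_r2_wins(self, rng):
        x = rng.standard_normal(100)
        y = 0.9 * x + 0.05 * rng.standard_normal(100)
        table = evaluate_models(x, y, n_repeats=2)
        best = select_best_model(table)
        assert best == table.loc[table["r2_score"].idxmax(), "model"]

    def test_single_row(self):
        import pandas as pd
        t = pd.DataFrame([("svr", 0.1, 0.1, 0.1, 0.5)],
                         columns=["model", "ev", "mae", "mse", "r2_score"])
        assert select_best_model(t) == "svr"

    def test_tie_breaks_on_lower_mse(self):
        import pandas as pd
        t = pd.DataFrame([("linear", 0.5, 0.1, 0.30, 0.5),
                          ("gbr", 0.5, 0.1, 0.20, 0.5)],
                         columns=["model", "ev", "mae", "mse", "r2_score"])
        assert select_best_model(t) == "gbr"

    def test_tie_breaks_on_model_order(self):
        import pandas as pd
        t = pd.DataFrame([("gbr", 0.5, 0.1, 0.2, 0.5),
                          ("linear", 0.5, 0.1, 0.2, 0.5)],
                         columns=["model", "ev", "mae", "mse", "r2_score"])
        assert select_best_model(t) == "linear"  # fixed order before gbr


class TestRunSyncMatrix:
    def test_full_matrix_and_planted_ranking(self):
        from eyesync import (CouplingSpec, SyntheticConfig, generate_session,
                             process_session, run_sync_matrix)
        from eyesync.pipeline import RunConfig

        synth = SyntheticConfig(
            n_subjects=1, n_videos=1, duration_s=300.0, seed=2,
            couplings=(CouplingSpec("pupil_right", "F3", "delta", 0.95),))
        cfg = RunConfig(synthetic=synth, window_s=20.0, split_mode="random")
        session = generate_session(synth, 0, 0)
        eye_ratios, eeg_ratios = process_session(
            session.eeg, session.gaze, cfg)
        spec = RegressionSpec(model="gbr", split_mode="random", seed=0)
        results = run_sync_matrix(eye_ratios, eeg_ratios, spec,
                                  label=session.label)
        assert len(results) == 288  # 4 features x 18 channels x 4 bands
        r2s = {(r.eye_feature, r.channel, r.band): r.r2 for r in results}
        planted = r2s[("pupil_right", "F3", "delta")]
        rank = sum(v >= planted for v in r2s.values())
        assert rank <= int(0.05 * len(r2s))  # top 5%
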