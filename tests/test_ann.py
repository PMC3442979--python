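import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fimsquant.ann import (
    ANNModel,
    NeuralCalibration,
    ann_predict,
    fit_metrics,
    kfold_select,
    tanh_activation,
    train_ann,
)

from conftest import SIX_LEVELS, single_analyte_matrix


def small_model(hidden=None, output=(0.0, 0.0, 0.0, 0.0), n_features=1):
    if hidden is None:
        hidden = np.zeros((3, 1 + n_features))
    return ANNModel(
        feature_mz=100.0 + np.arange(n_features),
        input_center=np.zeros(n_features),
        input_scale=np.ones(n_features),
        hidden_weights=hidden,
        output_weights=np.asarray(output, dtype=float),
    )


class TestTanh:
    def test_matches_printed_closed_form(self):
        x = np.linspace(-5, 5, 101)
        closed_form = (np.exp(2 * x) - 1) / (np.exp(2 * x) + 1)
        np.testing.assert_allclose(tanh_activation(x), closed_form, atol=1e-14)

    def test_zero_maps_to_zero(self):
        assert tanh_activation(0.0) == 0.0

    def test_half_log_three_maps_to_half(self):
        assert tanh_activation(0.5 * math.log(3)) == pytest.approx(0.5, abs=1e-15)

    def test_saturates_within_open_interval(self):
        assert tanh_activation(1e4) == pytest.approx(1.0)
        assert tanh_activation(-1e4) == pytest.approx(-1.0)
        x = np.linspace(-30, 30, 1001)
        y = tanh_activation(x)
        assert np.all(np.diff(y) >= 0)
        assert np.all(np.abs(y) <= 1.0)
        assert np.all(np.isfinite(y))

    def test_odd_function(self):
        x = np.linspace(0, 10, 50)
        np.testing.assert_allclose(tanh_activation(-x), -tanh_activation(x))


class TestPredict:
    def test_zero_weights_give_the_constant(self):
        model = small_model(output=(0.0, 0.0, 0.0, 7.5))
        np.testing.assert_allclose(model.predict([[123.0]]), [7.5])
        np.testing.assert_allclose(model.predict([[-1e9]]), [7.5])

    def test_hand_evaluated_closed_form(self):
        # H1 = tanh(0.5·(0 + ln3·1)) = (3−1)/(3+1) = 0.5; ŷ = 2·0.5 + 1 = 2
        hidden = np.array([[0.0, math.log(3)], [0.0, 0.0], [0.0, 0.0]])
        model = small_model(hidden=hidden, output=(2.0, 0.0, 0.0, 1.0))
        assert model.predict([[1.0]])[0] == pytest.approx(2.0, abs=1e-12)

    def test_length_mismatch_names_expected_features(self):
        model = small_model(n_features=2)
        with pytest.raises(ValueError, match="expected 2 channels"):
            ann_predict(model, [[1.0, 2.0, 3.0]])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_prediction_bounded_by_output_weights(self, x):
        rng = np.random.default_rng(5)
        model = small_model(
            hidden=rng.normal(size=(3, 3)), output=rng.normal(size=4), n_features=2
        )
        bound = np.abs(model.output_weights[:3]).sum() + abs(model.output_weights[3])
        assert abs(model.predict([x])[0]) <= bound + 1e-9


class TestFitMetrics:
    def test_perfect_prediction(self):
        r = fit_metrics([2.0, 20.0, 50.0], [2.0, 20.0, 50.0])
        assert r.rmse_percent == 0.0 and r.r_squared == 1.0

    def test_constant_offset_keeps_r_squared_one(self):
        r = fit_metrics([3.0, 21.0, 51.0], [2.0, 20.0, 50.0])
        assert r.r_squared == pytest.approx(1.0)
        assert r.rmse_percent > 0

    def test_hand_computed_normalized_rmse(self):
        actual = [2.0, 20.0, 50.0, 100.0, 200.0, 400.0]
        predicted = [2.0, 20.0, 50.0, 100.0, 200.0, 396.0]
        r = fit_metrics(predicted, actual)
        # RMSE = sqrt(16/6); mean = 128.667 → 1.269 %
        assert r.rmse_percent == pytest.approx(100 * math.sqrt(16 / 6) / (772 / 6), abs=1e-9)
        assert r.rmse_percent == pytest.approx(1.269, abs=5e-4)

    def test_zero_mean_actual_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_metrics([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0])

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_metrics([1.0, 2.0], [1.0, 2.0])

    def test_relative_variant(self):
        r = fit_metrics([1.1, 2.0, 4.0], [1.0, 2.0, 4.0], relative=True)
        assert r.rmse_percent == pytest.approx(100 * math.sqrt(0.01 / 3), rel=1e-9)


class TestTraining:
    def test_noise_free_training_error_below_a_tenth_percent(self, two_channel_fingerprint):
        m = single_analyte_matrix(two_channel_fingerprint, cv=0.0, seed=0, n_sets=1,
                                  background=0, baseline_mean=0.0, baseline_sd=0.0)
        X = m.feature_values(two_channel_fingerprint.mz)
        model = train_ann(X, m.row_concentration, seed=0, n_restarts=10,
                          feature_mz=two_channel_fingerprint.mz)
        pred = model.predict(X)
        rel = np.abs(pred - m.row_concentration) / m.row_concentration
        assert rel.max() < 1e-3

    def test_fit_is_deterministic(self, calibration_matrix):
        m = calibration_matrix
        X = m.values[:, m.column_scale > 0][:, :2]
        a = train_ann(X, m.row_concentration, seed=3, n_restarts=5)
        b = train_ann(X, m.row_concentration, seed=3, n_restarts=5)
        np.testing.assert_array_equal(a.hidden_weights, b.hidden_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)

    def test_row_permutation_leaves_predictions_unchanged(self, two_channel_fingerprint):
        m = single_analyte_matrix(two_channel_fingerprint, cv=0.0, seed=1,
                                  n_sets=1, background=0)
        X, y = m.feature_values(two_channel_fingerprint.mz), m.row_concentration
        perm = np.random.default_rng(0).permutation(len(y))
        a = train_ann(X, y, seed=2, n_restarts=5)
        b = train_ann(X[perm], y[perm], seed=2, n_restarts=5)
        np.testing.assert_allclose(a.predict(X), b.predict(X), rtol=1e-3, atol=1e-3)

    def test_requires_six_distinct_levels(self):
        with pytest.raises(ValueError, match="distinct concentration"):
            NeuralCalibration(np.arange(10.0)[:, None], np.repeat([1.0, 2.0], 5))

    def test_small_sample_regime_warns(self):
        y = np.tile(np.asarray(SIX_LEVELS), 2)
        X = np.column_stack([y * 3 + 1, y * 5 + 2, y * 7, y * 2 + 4])  # 19 params > 12 rows
        with pytest.warns(UserWarning, match="small-sample"):
            NeuralCalibration(X, y)

    def test_json_round_trip_preserves_predictions(self, tmp_path, calibration_matrix):
        m = calibration_matrix
        X = m.values[:, m.column_scale > 0][:, :2]
        model = train_ann(X, m.row_concentration, seed=1, n_restarts=4)
        model.to_json(tmp_path / "model.json")
        again = ANNModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(model.predict(X), again.predict(X))


class TestKFold:
    def make_xy(self, fingerprint, cv, seed, n_sets=1):
        m = single_analyte_matrix(fingerprint, cv=cv, seed=seed, n_sets=n_sets,
                                  background=0)
        return m.feature_values(fingerprint.mz), m.row_concentration

    def test_noise_free_validation_error_negligible(self, two_channel_fingerprint):
        X, y = self.make_xy(two_channel_fingerprint, 0.0, 0)
        model, train_rep, val_rep = kfold_select(X, y, k=5, seed=0, n_restarts=8)
        assert train_rep.rmse_percent < 0.1
        assert val_rep.rmse_percent < 0.1

    def test_leave_one_out_runs_on_thirty_rows(self, two_channel_fingerprint):
        X, y = self.make_xy(two_channel_fingerprint, 0.02, 3)
        assert len(y) == 30
        model, _, val_rep = kfold_select(X, y, k=30, seed=0, n_restarts=2)
        assert np.isfinite(val_rep.rmse_percent)

    def test_fold_with_single_level_is_an_error(self):
        y = np.asarray(SIX_LEVELS)
        X = (3 * y + 1)[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            with pytest.raises(ValueError, match="fewer than 2 distinct"):
                NeuralCalibration(X, y).fit_kfold(k=5, seed=0, n_restarts=2)

    def test_k_bounds_validated(self, two_channel_fingerprint):
        X, y = self.make_xy(two_channel_fingerprint, 0.0, 0)
        with pytest.raises(ValueError, match="≥ 2"):
            NeuralCalibration(X, y).fit_kfold(k=1)
        with pytest.raises(ValueError, match="exceeds"):
            NeuralCalibration(X, y).fit_kfold(k=31)

    def test_selection_is_deterministic(self, two_channel_fingerprint):
        X, y = self.make_xy(two_channel_fingerprint, 0.02, 5)
        a = NeuralCalibration(X, y).fit_kfold(k=5, seed=9, n_restarts=3)
        b = NeuralCalibration(X, y).fit_kfold(k=5, seed=9, n_restarts=3)
        assert a.fold_index == b.fold_index
        np.testing.assert_array_equal(
            a.results.model.hidden_weights, b.results.model.hidden_weights
        )
        assert a.validation_report == b.validation_report

    def test_validation_error_nondecreasing_in_noise(self, two_channel_fingerprint):
        """Seed-averaged validation RMSE% grows with replicate noise."""
        means = []
        for cv in (0.0, 0.01, 0.02, 0.05):
            vals = []
            for seed in range(10):
                X, y = self.make_xy(two_channel_fingerprint, cv, seed)
                sel = NeuralCalibration(X, y).fit_kfold(k=3, seed=seed, n_restarts=3)
                vals.append(sel.validation_report.rmse_percent)
            means.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_summary_mentions_architecture(self, two_channel_fingerprint):
        X, y = self.make_xy(two_channel_fingerprint, 0.0, 0)
        sel = NeuralCalibration(X, y, feature_mz=two_channel_fingerprint.mz).fit_kfold(
            k=3, seed=0, n_restarts=3
        )
        text = sel.summary()
        assert "3 tanh nodes" in text
        assert "validation" in text
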