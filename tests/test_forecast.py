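"""Forecast engines: embedding, simplex, selection, multiview, ARIMA, protocol."""

import numpy as np
import pytest

from microcast import forecast as fc
from microcast import metrics as mx
from microcast import preprocess as pp
from conftest import logistic_map


def brute_force_simplex(lib_X, lib_y, query, k):
    """Independent oracle: full distance list, explicit sort, explicit weights."""
    lib_X = np.atleast_2d(np.asarray(lib_X, float))
    q = np.atleast_1d(np.asarray(query, float))
    d = [float(np.sqrt(np.sum((row - q) ** 2))) for row in lib_X]
    order = sorted(range(len(d)), key=lambda i: d[i])[:k]
    dmin = d[order[0]]
    if dmin == 0.0:
        zeros = [i for i in range(len(d)) if d[i] == 0.0]
        return float(np.mean([lib_y[i] for i in zeros]))
    num = den = 0.0
    for i in order:
        w = np.exp(-d[i] / dmin)
        num += w * lib_y[i]
        den += w
    return num / den


class TestDelayEmbed:
    def test_hand_example(self):
        X, y, t = fc.delay_embed([1, 2, 3, 4, 5], E=2, tau=1)
        assert X.tolist() == [[2, 1], [3, 2], [4, 3]]
        assert y.tolist() == [3, 4, 5]
        assert t.tolist() == [1, 2, 3]

    def test_identity_embedding_at_E1(self):
        X, y, t = fc.delay_embed([1, 2, 3], E=1)
        assert X.tolist() == [[1], [2]]
        assert y.tolist() == [2, 3]

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            fc.delay_embed([1, 2, 3], E=3, tau=1)
        with pytest.raises(ValueError):
            fc.delay_embed([1, 2, 3, 4], E=2, tau=3)


class TestSimplexPredict:
    def test_exact_match_returns_successor(self):
        lib = [[1.0, 2.0], [3.0, 4.0], [0.0, 0.0]]
        assert fc.simplex_predict(lib, [0.7, 0.2, 0.9], [1.0, 2.0]) == 0.7

    def test_constant_targets_give_constant_prediction(self):
        rng = np.random.default_rng(0)
        lib = rng.random((10, 3))
        y = np.full(10, 0.42)
        assert fc.simplex_predict(lib, y, rng.random(3)) == pytest.approx(0.42)

    def test_prediction_within_neighbour_target_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lib = rng.normal(size=(30, 2))
            y = rng.normal(size=30)
            p = fc.simplex_predict(lib, y, rng.normal(size=2))
            assert y.min() - 1e-12 <= p <= y.max() + 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(5, 50)
            E = int(rng.integers(1, 4))
            lib = rng.normal(size=(n, E))
            y = rng.normal(size=n)
            q = rng.normal(size=E)
            assert fc.simplex_predict(lib, y, q, n_neighbors=E + 1) == pytest.approx(
                brute_force_simplex(lib, y, q, E + 1), abs=1e-12)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            fc.simplex_predict(np.empty((0, 2)), np.empty(0), [0.0, 0.0])


class TestSelectEmbeddingDim:
    def test_ar1_data_selects_small_dimension(self):
        """A strongly autocorrelated AR(1) has a one-dimensional state, so the
        leave-one-out selection concentrates on small embedding dimensions."""
        chosen = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = np.zeros(111)
            for i in range(1, 111):
                x[i] = 0.9 * x[i - 1] + rng.normal()
            chosen.append(fc.select_embedding_dim(x))
        assert np.median(chosen) <= 3

    def test_logistic_map_needs_more_than_one_lag(self):
        x = logistic_map(111)
        X1, y1, t1 = fc.delay_embed(x, 1)
        X2, y2, t2 = fc.delay_embed(x, 2)
        r1 = fc._loo_simplex_rmse(X1, y1, t1, theiler=1, k=2)
        r2 = fc._loo_simplex_rmse(X2, y2, t2, theiler=2, k=3)
        assert r2 < r1
        assert fc.select_embedding_dim(x) >= 2

    def test_tie_break_prefers_smallest_E(self):
        # constant-plus-tiny-deterministic series: all E equivalent
        x = np.concatenate([np.tile([0.0, 1.0], 60)])[:111]
        assert fc.select_embedding_dim(x) == 1


class TestArima:
    def test_white_noise_selects_empty_order(self):
        rng = np.random.default_rng(5)
        f = fc.ArimaForecaster().fit(rng.normal(0, 1, 111))
        assert f.order_ == (0, 0, 0)

    def test_ar1_coefficient_recovered(self):
        phis = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = np.zeros(111)
            for i in range(1, 111):
                x[i] = 0.8 * x[i - 1] + rng.normal()
            f = fc.ArimaForecaster(max_p=1, max_q=1).fit(x)
            if f.order_[0] >= 1:
                phis.append(f._res.arparams[0])
        assert abs(np.median(phis) - 0.8) < 0.15

    def test_one_step_predictions_use_observed_history(self):
        """Predictions for the test window condition on observed values, with
        parameters frozen: an AR(1) with known coefficient predicts phi*x[t-1]."""
        rng = np.random.default_rng(7)
        x = np.zeros(123)
        for i in range(1, 123):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        f = fc.ArimaForecaster(max_p=1, max_q=0).fit(x[:111])
        preds = f.predict_test(x, 111)
        assert len(preds) == 12
        phi = f._res.arparams[0]
        c = f._res.params[0]
        expected = c * (1 - phi) + phi * x[110:122]
        assert np.allclose(preds, expected, atol=1e-6)


class TestMultiview:
    def test_single_predictor_collapses_to_one_view(self):
        x = logistic_map(123)
        ts = pp.detrend_standardize(x)
        mv = fc.MultiviewForecaster(target="x").fit(ts.values[:111],
                                                    {"x": ts.values[:111]})
        assert len(mv.views_) == 1
        assert len(mv.top_views_) == 1

    def test_identical_views_average_to_same_prediction(self):
        x = logistic_map(123)
        ts = pp.detrend_standardize(x)
        res = fc.one_step_protocol(ts.values, "multiview", target="x",
                                   predictors={"x": ts.values})
        single = fc.one_step_protocol(ts.values, "multiview", target="x",
                                      predictors={"x": ts.values})
        assert np.allclose(res.predictions, single.predictions)

    def test_cross_variable_information_helps_driven_variable(self):
        """Coupled logistic maps: multiview in-train-selected ensemble beats
        univariate simplex on the driven variable (20-seed median)."""
        diffs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = np.empty(123)
            y = np.empty(123)
            x[0], y[0] = 0.4, 0.2
            for i in range(1, 123):
                x[i] = x[i - 1] * (3.8 - 3.8 * x[i - 1] - 0.02 * y[i - 1])
                y[i] = y[i - 1] * (3.5 - 3.5 * y[i - 1] - 0.1 * x[i - 1])
            tsy = pp.detrend_standardize(y + rng.normal(0, 0.02, 123))
            tsx = pp.detrend_standardize(x)
            r_uni = fc.one_step_protocol(tsy.values, "simplex").rmse_std
            r_mv = fc.one_step_protocol(
                tsy.values, "multiview", target="y",
                predictors={"x": tsx.values, "y": tsy.values}).rmse_std
            diffs.append(r_mv - r_uni)
        assert np.median(diffs) <= 0.0

    def test_no_valid_view_rejected(self):
        with pytest.raises(ValueError):
            fc.MultiviewForecaster(target="x", view_dim=5, max_lag=0).fit(
                np.random.default_rng(0).random(111), {})


class TestOneStepProtocol:
    def test_exactly_twelve_predictions(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 123)
        ts = pp.detrend_standardize(x)
        for method in ("mean", "simplex", "arima"):
            res = fc.one_step_protocol(ts.values, method, transformed=ts)
            assert len(res.predictions) == 12
            assert res.rmse_std >= 0
            assert res.rmse_orig is not None

    def test_mean_baseline_rmse_one_on_full_series(self):
        rng = np.random.default_rng(9)
        ts = pp.detrend_standardize(rng.normal(3, 2, 123) + 0.1 * np.arange(123))
        preds = fc.MeanForecaster().fit(ts.values[:111]).predict_test(ts.values, 0)
        assert mx.rmse(preds, ts.values) == pytest.approx(1.0, abs=1e-12)

    def test_periodic_series_forecast_exactly(self):
        x = np.tile(np.array([0.1, 0.9, 0.4]), 41)
        ts_vals = (x - x.mean()) / x.std()
        res = fc.one_step_protocol(ts_vals, "simplex")
        assert res.rmse_std == pytest.approx(0.0, abs=1e-12)

    def test_no_hyperparameter_leakage_from_test_window(self):
        """Two series identical over the training window but different in the
        test window must receive identical selected hyperparameters."""
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 123)
        b = a.copy()
        b[111:] = rng.normal(0, 1, 12) + 5.0
        for method in ("simplex", "arima"):
            ra = fc.one_step_protocol(a, method)
            rb = fc.one_step_protocol(b, method)
            assert ra.hyperparams == rb.hyperparams

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fc.one_step_protocol(np.zeros(123), "oracle")

    def test_growing_library_uses_test_prefix(self):
        """On a stochastic series the growing library adds test-prefix states
        to the neighbour pool, changing (at least some) predictions."""
        rng = np.random.default_rng(12)
        x = np.zeros(123)
        for i in range(1, 123):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        ts = pp.detrend_standardize(x)
        frozen = fc.one_step_protocol(ts.values, "simplex", library="frozen")
        growing = fc.one_step_protocol(ts.values, "simplex", library="growing")
        assert len(growing.predictions) == 12
        assert frozen.hyperparams["E"] == growing.hyperparams["E"]
        assert not np.allclose(frozen.predictions, growing.predictions)
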