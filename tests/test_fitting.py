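"""Tests of relative-error fitting, backtesting, prediction, correlation."""

import math

import numpy as np
import pytest

from fraclake.errors import DomainError, ValidationError
from fraclake.fitting import (
    BacktestResult,
    ConcentrationSeries,
    backtest,
    correlate_media,
    epsilon2,
    fit_model,
    predict,
)
from fraclake.models import FDMParams, TDMParams
from fraclake.synthetic import SyntheticSpec, default_fdm_truth, generate_series


def make_series(t, v, **kw):
    return ConcentrationSeries(np.asarray(t, float), np.asarray(v, float), **kw)


class TestSeriesValidation:
    def test_requires_increasing_times(self):
        with pytest.raises(ValidationError):
            make_series([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValidationError, match="divides"):
            make_series([1.0, 2.0], [5.0, 0.0])

    def test_rejects_negative_times(self):
        with pytest.raises(ValidationError):
            make_series([-1.0, 2.0], [5.0, 5.0])

    def test_medium_checked(self):
        with pytest.raises(ValidationError):
            make_series([1.0], [1.0], medium="sediment")


class TestEpsilon2:
    def test_perfect_prediction(self):
        s = make_series([1, 2, 3], [10.0, 20.0, 30.0])
        assert epsilon2(s, [10.0, 20.0, 30.0]) == 0.0

    def test_single_point(self):
        s = make_series([1], [100.0])
        assert epsilon2(s, [90.0]) == pytest.approx(0.01, rel=1e-14)

    def test_two_points(self):
        s = make_series([1, 2], [2.0, 4.0])
        assert epsilon2(s, [1.0, 5.0]) == pytest.approx(0.3125, rel=1e-14)

    def test_unit_invariance(self):
        s1 = make_series([1, 2, 3], [2.0, 4.0, 8.0])
        s2 = make_series([1, 2, 3], [2000.0, 4000.0, 8000.0])
        p = np.array([1.9, 4.4, 7.0])
        assert epsilon2(s1, p) == pytest.approx(epsilon2(s2, 1000.0 * p), rel=1e-14)

    def test_length_mismatch(self):
        s = make_series([1, 2], [1.0, 2.0])
        with pytest.raises(ValidationError):
            epsilon2(s, [1.0])


class TestFitFDM:
    def test_noiseless_recovery(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
        fit = fit_model(s, "fdm")
        assert fit.converged
        assert abs(fit.params["alpha"] - 0.62) < 1e-3
        assert abs(fit.params["theta"] / truth.theta - 1.0) < 1e-3
        assert fit.epsilon2 < 1e-10

    def test_noiseless_recovery_on_alpha_grid(self):
        for alpha in (0.4, 0.62, 0.85):
            truth = FDMParams(A=1256.0, alpha=alpha, theta=5.0 * 693.0 ** (-alpha))
            s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
            fit = fit_model(s, "fdm")
            assert abs(fit.params["alpha"] - alpha) < 1e-3
            assert abs(fit.params["theta"] / truth.theta - 1.0) < 1e-3

    def test_objective_never_worse_than_start(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.1, seed=5))
        init = {"A": float(s.values[0]), "alpha": 0.5, "theta": 0.01}
        fit = fit_model(s, "fdm", init=init)
        from fraclake.models import c_fdm

        start = epsilon2(
            s, c_fdm(s.t_days, FDMParams(A=init["A"], alpha=0.5, theta=0.01))
        )
        assert fit.epsilon2 <= start + 1e-12

    def test_xi_reporting_convention(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
        fit = fit_model(s, "fdm", fixed={"tau": 693.0})
        assert fit.params["xi"] == pytest.approx(5.00, rel=1e-3)

    def test_fixed_A(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
        fit = fit_model(s, "fdm", fixed={"A": 1256.0})
        assert fit.params["A"] == 1256.0
        assert abs(fit.params["alpha"] - 0.62) < 1e-6

    def test_flat_series_flagged_not_crashed(self):
        s = make_series(np.linspace(100, 1000, 10), np.full(10, 50.0))
        fit = fit_model(s, "fdm")
        assert fit.at_bound or not fit.converged

    def test_too_few_points(self):
        s = make_series([1, 2, 3], [3.0, 2.0, 1.0])
        with pytest.raises(ValidationError):
            fit_model(s, "fdm")

    def test_unknown_model(self):
        s = make_series([1, 2, 3, 4, 5], [5.0, 4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValidationError):
            fit_model(s, "exponential-cascade")


class TestFitTDM:
    TRUTH = TDMParams(Q1=300.0, k1=8e-3, Q2=80.0, k2=4e-4)

    def test_noiseless_recovery(self):
        s = generate_series(SyntheticSpec(params=self.TRUTH, noise_sd_rel=0.0))
        fit = fit_model(s, "tdm")
        assert fit.epsilon2 < 1e-12
        assert fit.params["Q1"] == pytest.approx(300.0, rel=1e-4)
        assert fit.params["k1"] == pytest.approx(8e-3, rel=1e-4)
        assert fit.params["Q2"] == pytest.approx(80.0, rel=1e-4)
        assert fit.params["k2"] == pytest.approx(4e-4, rel=1e-4)

    def test_component_ordering_convention(self):
        s = generate_series(SyntheticSpec(params=self.TRUTH, noise_sd_rel=0.0))
        fit = fit_model(s, "tdm")
        assert fit.params["k1"] >= fit.params["k2"]

    def test_sdm(self):
        truth = TDMParams(Q1=200.0, k1=2e-3)
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
        fit = fit_model(s, "sdm")
        assert fit.epsilon2 < 1e-18
        assert fit.params["Q1"] == pytest.approx(200.0, rel=1e-6)


class TestBacktest:
    def test_heldout_epsilon2_matches_direct_summation(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.1, seed=3))
        bt = backtest(s, 1527.0, "fdm")
        assert isinstance(bt, BacktestResult)
        # independent recomputation of the held-out squared relative error
        mask = s.t_days > 1527.0
        pred = predict(bt.train.to_params(), s.t_days[mask])
        direct = math.fsum(
            ((m - p) / m) ** 2 for m, p in zip(s.values[mask], pred)
        )
        assert bt.epsilon2_test == pytest.approx(direct, rel=1e-13)
        assert bt.n_test == int(mask.sum())

    def test_train_window_includes_split_day(self):
        t = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        v = 100.0 * np.exp(-1e-3 * t)
        s = make_series(t, v)
        bt = backtest(s, 500.0, "sdm")
        assert bt.train.n_points == 5
        assert bt.n_test == 1

    def test_split_outside_range_rejected(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.0))
        with pytest.raises(ValidationError):
            backtest(s, 5000.0, "fdm")
        with pytest.raises(ValidationError):
            backtest(s, 10.0, "fdm")

    def test_test_error_comparable_to_train_on_clean_data(self):
        truth = default_fdm_truth()
        s = generate_series(SyntheticSpec(params=truth, noise_sd_rel=0.05, seed=11))
        bt = backtest(s, 1527.0, "fdm")
        per_point_train = bt.train.epsilon2 / bt.train.n_points
        per_point_test = bt.epsilon2_test / bt.n_test
        # held-out error per point should be the same order as train error
        assert per_point_test < 20.0 * max(per_point_train, 1e-4)


class TestPredict:
    def test_fdm_long_horizon_slope(self):
        p = FDMParams(A=1256.0, alpha=0.62, theta=5.0 * 693.0 ** (-0.62), lambda_d=0.0)
        t = np.geomspace(693e3, 693e5, 50)
        curve = predict(p, t)
        slope = np.polyfit(np.log(t), np.log(curve), 1)[0]
        assert abs(slope + 0.62) < 0.03

    def test_tdm_long_horizon_dominated_by_slow_component(self):
        p = TDMParams(Q1=300.0, k1=8e-3, Q2=80.0, k2=1e-4)
        t = np.array([20000.0, 40000.0])
        curve = predict(p, t)
        np.testing.assert_allclose(curve, 80.0 * np.exp(-1e-4 * t), rtol=1e-6)

    def test_value_at_origin(self):
        fdm = default_fdm_truth()
        assert predict(fdm, [0.0])[0] == pytest.approx(1256.0, rel=1e-12)
        tdm = TDMParams(Q1=300.0, k1=8e-3, Q2=80.0, k2=1e-4)
        assert predict(tdm, [0.0])[0] == 380.0

    def test_negative_times_rejected(self):
        with pytest.raises(DomainError):
            predict(default_fdm_truth(), [-1.0, 5.0])


class TestCorrelation:
    def test_proportional_series(self):
        w = make_series([1, 2, 3, 4], [10.0, 8.0, 6.0, 4.0])
        f = make_series([1, 2, 3, 4], [20.0, 16.0, 12.0, 8.0], medium="fish")
        assert correlate_media(w, f) == pytest.approx(1.0, abs=1e-12)

    def test_antiproportional_series(self):
        w = make_series([1, 2, 3, 4], [10.0, 8.0, 6.0, 4.0])
        f = make_series([1, 2, 3, 4], [90.0, 92.0, 94.0, 96.0], medium="fish")
        assert correlate_media(w, f) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(42)
        t = np.arange(10, dtype=float)
        wv = 100.0 * np.exp(-0.1 * t)
        fv = 2.0 * wv * np.exp(rng.normal(0, 0.2, 10))
        w = make_series(t, wv)
        f = make_series(t, fv, medium="fish")
        x, y = wv, fv
        r_direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert correlate_media(w, f) == pytest.approx(r_direct, abs=1e-12)

    def test_pairing_window_respected(self):
        w = make_series([0.0, 100.0, 200.0, 300.0], [4.0, 3.0, 2.0, 1.0])
        f = make_series([0.0, 101.0, 199.0], [8.0, 6.0, 4.0], medium="fish")
        # window 30: three pairs; window 0.5: only one -> error
        assert correlate_media(w, f, pairing_window=30.0) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValidationError):
            correlate_media(w, f, pairing_window=0.5)
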