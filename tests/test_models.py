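"""Tests of the forward prediction models and derived physical quantities."""

import math

import numpy as np
import pytest

from fraclake.errors import DomainError
from fraclake.mittag_leffler import MLSettings, ml_neg
from fraclake.models import (
    CS137_HALF_LIFE_DAYS,
    CS137_LAMBDA_D,
    BulgakovParams,
    DiffusionScales,
    FDMParams,
    TDMParams,
    c_bulgakov_approx,
    c_bulgakov_full,
    c_fdm,
    c_tdm,
    decay_constant,
    initial_concentration_estimate,
    k_alpha,
)

LAKE_WATER = FDMParams.from_xi_tau(A=1256.0, alpha=0.62, xi=5.00, tau=693.0)


class TestFDM:
    def test_initial_value(self):
        assert c_fdm(0.0, LAKE_WATER) == pytest.approx(1256.0, rel=1e-12)

    def test_lake_water_parameters_at_tau(self):
        # at t = tau the Mittag-Leffler argument is exactly xi = 5;
        # 1256 * E_0.62(-5) * exp(-693 * lambda_d), E value from the
        # high-precision oracle
        expected = 1256.0 * 0.091776956647740538 * math.exp(-693.0 * CS137_LAMBDA_D)
        assert c_fdm(693.0, LAKE_WATER) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(110.3406348756417, rel=1e-12)

    @pytest.mark.parametrize("c", [0.1, 2.0, 10.0])
    def test_gauge_invariance(self, c):
        # (xi, tau) -> (c xi, c^(1/alpha) tau) leaves the curve unchanged
        alt = FDMParams.from_xi_tau(
            A=1256.0, alpha=0.62, xi=5.00 * c, tau=693.0 * c ** (1 / 0.62)
        )
        t = np.geomspace(1.0, 1e4, 50)
        np.testing.assert_allclose(c_fdm(t, alt), c_fdm(t, LAKE_WATER), rtol=1e-12)

    def test_strictly_decreasing(self):
        t = np.linspace(0.0, 5000.0, 200)
        vals = c_fdm(t, LAKE_WATER)
        assert np.all(np.diff(vals) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            c_fdm(-1.0, LAKE_WATER)

    def test_long_time_power_law_slope(self):
        p = FDMParams(A=1256.0, alpha=0.62, theta=LAKE_WATER.theta, lambda_d=0.0)
        t = np.geomspace(693e3, 693e5, 60)
        slope = np.polyfit(np.log(t), np.log(c_fdm(t, p)), 1)[0]
        assert slope == pytest.approx(-0.62, abs=0.02)

    def test_param_invariants(self):
        with pytest.raises(DomainError):
            FDMParams(A=-1.0, alpha=0.62, theta=0.1)
        with pytest.raises(DomainError):
            FDMParams(A=1.0, alpha=1.0, theta=0.1)
        with pytest.raises(DomainError):
            FDMParams.from_xi_tau(A=1.0, alpha=0.62, xi=0.0, tau=693.0)

    def test_xi_tau_roundtrip(self):
        assert LAKE_WATER.xi_for_tau(693.0) == pytest.approx(5.00, rel=1e-14)


class TestTDM:
    def test_initial_value(self):
        p = TDMParams(Q1=300.0, k1=0.01, Q2=80.0, k2=5e-4)
        assert c_tdm(0.0, p) == 380.0

    def test_direct_arithmetic(self):
        p = TDMParams(Q1=300.0, k1=0.01, Q2=80.0, k2=5e-4)
        assert c_tdm(100.0, p) == pytest.approx(186.46218631148982, rel=1e-14)

    def test_single_component_reduction(self):
        p = TDMParams(Q1=300.0, k1=0.01)
        t = np.linspace(0, 1000, 20)
        np.testing.assert_allclose(c_tdm(t, p), 300.0 * np.exp(-0.01 * t), rtol=1e-15)

    def test_sum_of_two_order_one_mittag_leffler_terms(self):
        # the two-exponential model is exactly two alpha=1 relaxations
        p = TDMParams(Q1=300.0, k1=0.01, Q2=80.0, k2=5e-4)
        for t in (0.0, 100.0, 2500.0):
            ml_form = p.Q1 * ml_neg(1.0, p.k1 * t) + p.Q2 * ml_neg(1.0, p.k2 * t)
            assert c_tdm(t, p) == ml_form

    def test_ordering_enforced(self):
        with pytest.raises(DomainError):
            TDMParams(Q1=1.0, k1=0.001, Q2=1.0, k2=0.01)
        p = TDMParams.ordered(1.0, 0.001, 2.0, 0.01)
        assert p.k1 == 0.01 and p.Q1 == 2.0


class TestBulgakov:
    P = BulgakovParams(sigma_d=20000.0, h_w=10.0, K_d=200.0, D_E=1e-5)

    def test_initial_value(self):
        assert c_bulgakov_full(0.0, self.P) == pytest.approx(2000.0, rel=1e-14)

    def test_equals_half_order_fdm(self):
        # exact sediment-exchange solution == alpha = 1/2 fractional model
        zfac = self.P.K_d * math.sqrt(self.P.D_E) / self.P.h_w
        fdm = FDMParams(
            A=self.P.sigma_d / self.P.h_w,
            alpha=0.5,
            theta=zfac,
            lambda_d=self.P.lambda_d,
        )
        tight = MLSettings(series_tol=1e-16, quad_rel_tol=1e-12)
        t = np.geomspace(1.0, 1e4, 80)
        np.testing.assert_allclose(
            c_fdm(t, fdm, tight), c_bulgakov_full(t, self.P), rtol=1e-10
        )

    def test_approx_examples(self):
        assert c_bulgakov_approx(4.0, 100.0, 0.0) == 50.0
        assert c_bulgakov_approx(16.0, 100.0, 0.0) == 25.0

    def test_approx_matches_full_at_large_z(self):
        zfac = self.P.K_d * math.sqrt(self.P.D_E) / self.P.h_w
        A_B = self.P.sigma_d / (self.P.h_w * math.sqrt(math.pi) * zfac)
        t = (25.0 / zfac) ** 2  # z = 25
        assert c_bulgakov_approx(t, A_B, self.P.lambda_d) == pytest.approx(
            c_bulgakov_full(t, self.P), rel=0.01
        )

    def test_approx_singular_at_zero(self):
        with pytest.raises(DomainError):
            c_bulgakov_approx(0.0, 100.0, 0.0)


class TestScalarHelpers:
    def test_decay_constant_cs137(self):
        lam = decay_constant(30.08 * 365.25)
        assert lam == pytest.approx(6.3089e-5, rel=1e-4)
        assert lam == CS137_LAMBDA_D
        assert CS137_HALF_LIFE_DAYS == pytest.approx(10986.72)

    def test_decay_constant_roundtrip(self):
        assert decay_constant(math.log(2.0)) == pytest.approx(1.0, rel=1e-15)
        t_half = 123.4
        assert decay_constant(t_half) * t_half == pytest.approx(math.log(2.0))

    def test_decay_constant_domain(self):
        with pytest.raises(DomainError):
            decay_constant(0.0)

    def test_initial_concentration(self):
        assert initial_concentration_estimate(20000.0, 1e6, 1e7) == 2000.0
        assert initial_concentration_estimate(40000.0, 1e6, 1e7) == 4000.0
        assert initial_concentration_estimate(20000.0, 2e6, 1e7) == 4000.0
        with pytest.raises(DomainError):
            initial_concentration_estimate(0.0, 1e6, 1e7)

    def test_k_alpha_and_xi(self):
        s = DiffusionScales(sigma2=1.0, mu1=1.0)
        for alpha in (0.3, 0.62, 1.0):
            assert k_alpha(s, 1.0, alpha) == 1.0
        s2 = DiffusionScales(sigma2=2.0, mu1=3.0)
        assert s2.xi == 18.0

    def test_theta_invariance_algebra(self):
        alpha = 0.62
        base = FDMParams.from_xi_tau(A=1.0, alpha=alpha, xi=5.0, tau=693.0)
        for c in (0.1, 2.0, 10.0):
            scaled = FDMParams.from_xi_tau(
                A=1.0, alpha=alpha, xi=c * 5.0, tau=693.0 * c ** (1 / alpha)
            )
            assert scaled.theta == pytest.approx(base.theta, rel=1e-12)
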