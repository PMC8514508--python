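"""Forward prediction models for radiocesium activity concentration.

Four model families describe the decline of the 137Cs activity
concentration C(t) in a closed lake (Bq m^-3 of water, or Bq kg^-1 wet
weight of fish) after a single deposition event at t = 0:

* FDM, the fractional diffusion model:
      C(t) = A * E_alpha(-xi * (t/tau)^alpha) * exp(-lambda_d * t),
  the spatially averaged fundamental mode of a time-fractional
  diffusion equation.  A is the initial average activity concentration,
  alpha the anomalous-diffusion exponent, tau the waiting-time scale
  (days) and xi = mu1^2 * sigma^2 a dimensionless mode-scale parameter.
  The output depends on (xi, tau) only through theta = xi * tau^-alpha,
  so the canonical internal parametrisation is (A, alpha, theta,
  lambda_d).
* TDM / SDM, the two-component (single-component) decay-function model:
      C(t) = Q1*exp(-k1*t) + Q2*exp(-k2*t),
  with effective rates k that absorb radioactive decay.
* The Bulgakov sediment-exchange model, whose exact form
      C(t) = (sigma_d / h_w) * exp(z^2)*erfc(z) * exp(-lambda_d*t),
      z = (K_d * sqrt(D_E) / h_w) * sqrt(t),
  is the alpha = 1/2 special case of the FDM; its large-z approximation
  is A_B * t^(-1/2) * exp(-lambda_d * t).

lambda_d is the 137Cs radioactive decay constant; the default half-life
is 30.08 years (365.25-day years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import DomainError
from .mittag_leffler import DEFAULT_SETTINGS, MLSettings, ml_neg_vec

__all__ = [
    "CS137_HALF_LIFE_DAYS",
    "CS137_LAMBDA_D",
    "FDMParams",
    "TDMParams",
    "BulgakovParams",
    "DiffusionScales",
    "c_fdm",
    "c_tdm",
    "c_bulgakov_full",
    "c_bulgakov_approx",
    "decay_constant",
    "initial_concentration_estimate",
    "k_alpha",
]


def decay_constant(half_life_days: float) -> float:
    """Radioactive decay constant ln(2)/T_half in day^-1."""
    if not half_life_days > 0:
        raise DomainError(f"half-life must be positive, got {half_life_days}")
    return math.log(2.0) / half_life_days


#: 137Cs half-life, days (30.08 years of 365.25 days).
CS137_HALF_LIFE_DAYS = 30.08 * 365.25
#: 137Cs decay constant, day^-1.
CS137_LAMBDA_D = decay_constant(CS137_HALF_LIFE_DAYS)


@dataclass(frozen=True)
class FDMParams:
    """Fractional-diffusion-model parameters in canonical form.

    Attributes
    ----------
    A : float
        Initial average activity concentration (Bq m^-3 or Bq kg^-1).
    alpha : float
        Anomalous-diffusion exponent, strictly inside (0, 1).
    theta : float
        Relaxation-rate scale theta = xi * tau^-alpha (day^-alpha); the
        only combination of xi and tau the model output depends on.
    lambda_d : float
        Radioactive decay constant (day^-1); >= 0.
    """

    A: float
    alpha: float
    theta: float
    lambda_d: float = CS137_LAMBDA_D

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise DomainError(f"A must be positive, got {self.A}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.theta > 0:
            raise DomainError(f"theta must be positive, got {self.theta}")
        if self.lambda_d < 0:
            raise DomainError(f"lambda_d must be >= 0, got {self.lambda_d}")

    @classmethod
    def from_xi_tau(
        cls,
        A: float,
        alpha: float,
        xi: float,
        tau: float,
        lambda_d: float = CS137_LAMBDA_D,
    ) -> "FDMParams":
        """Construct from the (xi, tau) pair of the physical derivation."""
        if not xi > 0:
            raise DomainError(f"xi must be positive, got {xi}")
        if not tau > 0:
            raise DomainError(f"tau must be positive, got {tau}")
        return cls(A=A, alpha=alpha, theta=xi * tau ** (-alpha), lambda_d=lambda_d)

    def xi_for_tau(self, tau: float) -> float:
        """Report xi under the convention of a fixed, user-supplied tau.

        (xi, tau) are not separately identifiable from concentration
        data: any rescaling (xi, tau) -> (c*xi, c^(1/alpha)*tau) leaves
        the model curve unchanged.
        """
        if not tau > 0:
            raise DomainError(f"tau must be positive, got {tau}")
        return self.theta * tau**self.alpha


@dataclass(frozen=True)
class TDMParams:
    """Two-component decay-function-model parameters.

    Components are stored fast-first: k1 >= k2 >= 0, Q1, Q2 >= 0.  The
    rates are effective, i.e. they include radioactive decay; no second
    decay factor is applied.  Q2 = 0 gives the single-component model.
    """

    Q1: float
    k1: float
    Q2: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if self.Q1 < 0 or self.Q2 < 0:
            raise DomainError("component amplitudes must be non-negative")
        if self.k1 < 0 or self.k2 < 0:
            raise DomainError("component rates must be non-negative")
        if self.k1 < self.k2:
            raise DomainError("canonical ordering requires k1 >= k2 (fast first)")

    @classmethod
    def ordered(cls, Q1, k1, Q2, k2) -> "TDMParams":
        """Construct with automatic fast-first component ordering."""
        if k1 >= k2:
            return cls(Q1=Q1, k1=k1, Q2=Q2, k2=k2)
        return cls(Q1=Q2, k1=k2, Q2=Q1, k2=k1)


@dataclass(frozen=True)
class BulgakovParams:
    """Physical parameters of the Bulgakov sediment-exchange model.

    sigma_d: radionuclide deposition density (Bq m^-2); h_w: average
    water-column depth (m); K_d: dimensionless sediment-water
    distribution coefficient; D_E: effective diffusion coefficient in
    sediments (m^2 day^-1); lambda_d: decay constant (day^-1).
    """

    sigma_d: float
    h_w: float
    K_d: float
    D_E: float
    lambda_d: float = CS137_LAMBDA_D

    def __post_init__(self) -> None:
        for name in ("sigma_d", "h_w", "K_d", "D_E"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if self.lambda_d < 0:
            raise DomainError("lambda_d must be >= 0")

    def z(self, t) -> np.ndarray:
        """Dimensionless depth-exchange variable z(t) = K_d sqrt(D_E) / h_w * sqrt(t)."""
        t = np.asarray(t, dtype=float)
        return self.K_d * np.sqrt(self.D_E) / self.h_w * np.sqrt(t)


@dataclass(frozen=True)
class DiffusionScales:
    """Microscopic scales of the underlying random walk.

    sigma2: variance parameter of the jump-length distribution (m^2);
    mu1: fundamental spatial eigenvalue (m^-1), set by the water depth.
    """

    sigma2: float
    mu1: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise DomainError("sigma2 must be positive")
        if not self.mu1 > 0:
            raise DomainError("mu1 must be positive")

    @property
    def xi(self) -> float:
        """Mode-scale parameter xi = mu1^2 * sigma^2 (dimensionless)."""
        return self.mu1**2 * self.sigma2


def k_alpha(scales: DiffusionScales, tau: float, alpha: float) -> float:
    """Generalised diffusion coefficient K_alpha = sigma^2 / tau^alpha
    (m^2 day^-alpha)."""
    if not tau > 0:
        raise DomainError(f"tau must be positive, got {tau}")
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    return scales.sigma2 / tau**alpha


def _check_times(t, allow_zero=True) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if allow_zero:
        if np.any(t < 0):
            raise DomainError("times must be non-negative")
    else:
        if np.any(t <= 0):
            raise DomainError("times must be strictly positive")
    return t


def c_fdm(t, p: FDMParams, settings: MLSettings = DEFAULT_SETTINGS):
    """FDM activity concentration at time t (days).

    C(t) = A * E_alpha(-theta * t^alpha) * exp(-lambda_d * t), with the
    Mittag-Leffler factor evaluated through the dispatching numerics of
    :mod:`fraclake.mittag_leffler`.  Accepts scalars or arrays.
    """
    t = _check_times(t)
    scalar = t.ndim == 0
    tv = np.atleast_1d(t)
    y = p.theta * tv**p.alpha
    out = p.A * ml_neg_vec(p.alpha, y, settings) * np.exp(-p.lambda_d * tv)
    return float(out[0]) if scalar else out


def c_tdm(t, p: TDMParams):
    """TDM activity concentration Q1 e^{-k1 t} + Q2 e^{-k2 t}."""
    t = _check_times(t)
    out = p.Q1 * np.exp(-p.k1 * t) + p.Q2 * np.exp(-p.k2 * t)
    return float(out) if np.ndim(out) == 0 else out


def c_bulgakov_full(t, p: BulgakovParams):
    """Exact Bulgakov-model concentration (defined at t = 0).

    (sigma_d / h_w) * erfcx(z) * exp(-lambda_d t) with
    erfcx(z) = exp(z^2) erfc(z) the scaled complementary error function,
    which avoids the exp(z^2)/erfc cancellation at large z.
    """
    t = _check_times(t, allow_zero=True)
    z = p.z(t)
    out = p.sigma_d / p.h_w * special.erfcx(z) * np.exp(-p.lambda_d * t)
    return float(out) if np.ndim(out) == 0 else out


def c_bulgakov_approx(t, A_B: float, lambda_d: float = CS137_LAMBDA_D):
    """Large-time Bulgakov approximation A_B * t^(-1/2) * exp(-lambda_d t).

    Singular at t = 0; strictly positive times required.
    """
    if not A_B > 0:
        raise DomainError(f"A_B must be positive, got {A_B}")
    t = _check_times(t, allow_zero=False)
    out = A_B / np.sqrt(t) * np.exp(-lambda_d * t)
    return float(out) if np.ndim(out) == 0 else out


def initial_concentration_estimate(
    inventory_areal: float, bottom_area: float, volume: float
) -> float:
    """Initial whole-lake concentration from a sediment inventory.

    inventory_areal (Bq m^-2) times the lake-bottom area (m^2), diluted
    into the total water volume (m^3); returns Bq m^-3.
    """
    for name, v in (
        ("inventory_areal", inventory_areal),
        ("bottom_area", bottom_area),
        ("volume", volume),
    ):
        if not v > 0:
            raise DomainError(f"{name} must be positive, got {v}")
    return inventory_areal * bottom_area / volume
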