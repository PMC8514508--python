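"""Model fitting, backtesting and prediction for concentration series.

All models are fitted by minimising the squared relative error

    eps^2 = sum_i ((C_m_i - C(t_i)) / C_m_i)^2

with the Levenberg-Marquardt algorithm on the residual vector
r_i = (C_m_i - C(t_i)) / C_m_i.  The relative-error loss is the natural
objective for concentrations spanning an order of magnitude with
multiplicative measurement noise, and makes eps^2 invariant under a
change of concentration units.

Positivity and range constraints are enforced by smooth
reparametrisation (log for scales and amplitudes, scaled logit for the
anomalous-diffusion exponent alpha), so the internal optimisation stays
unconstrained and plain Levenberg-Marquardt applies.  The radioactive
decay constant lambda_d is held fixed during fitting: it is a nuclide
constant, not a free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, ValidationError
from .mittag_leffler import DEFAULT_SETTINGS, MLSettings
from .models import (
    CS137_LAMBDA_D,
    BulgakovParams,
    FDMParams,
    TDMParams,
    c_bulgakov_approx,
    c_bulgakov_full,
    c_fdm,
    c_tdm,
)

__all__ = [
    "ConcentrationSeries",
    "FitResult",
    "BacktestResult",
    "epsilon2",
    "fit_model",
    "backtest",
    "predict",
    "correlate_media",
]

MODELS = ("fdm", "tdm", "sdm", "bulgakov")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Timestamped activity concentrations for one medium.

    t_days are days since the release (strictly increasing, >= 0);
    values are strictly positive concentrations, Bq m^-3 for water or
    Bq kg^-1 wet weight for fish.  Zero or negative measurements are
    rejected outright: the relative-error objective divides by the
    measured value.
    """

    t_days: np.ndarray
    values: np.ndarray
    medium: str = "water"
    origin_date: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t_days", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValidationError("t_days and values must be 1-d arrays of equal length")
        if t.size and np.any(t < 0):
            raise ValidationError("sampling times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        bad = np.nonzero(~(v > 0))[0]
        if bad.size:
            raise ValidationError(
                f"non-positive concentration at index {bad[0]} "
                f"(t={t[bad[0]]}): relative-error fitting divides by the "
                "measured value"
            )
        if self.medium not in ("water", "fish"):
            raise ValidationError(f"medium must be 'water' or 'fish', got {self.medium!r}")

    def __len__(self) -> int:
        return int(self.t_days.size)

    def restrict(self, mask: np.ndarray) -> "ConcentrationSeries":
        return ConcentrationSeries(
            self.t_days[mask], self.values[mask], self.medium, self.origin_date
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit.

    ``params`` holds the canonical parametrisation (for the FDM:
    A, alpha, theta, lambda_d).  ``at_bound`` flags fits driven to the
    edge of the alpha box, which signals a degenerate series rather
    than a meaningful exponent.
    """

    model: str
    params: dict
    epsilon2: float
    n_points: int
    converged: bool
    n_iterations: int
    grad_norm: float
    at_bound: bool = False
    message: str = ""

    def to_params(self):
        """Rebuild the typed parameter object for forward prediction."""
        p = self.params
        if self.model == "fdm":
            return FDMParams(A=p["A"], alpha=p["alpha"], theta=p["theta"],
                             lambda_d=p["lambda_d"])
        if self.model in ("tdm", "sdm"):
            return TDMParams.ordered(p["Q1"], p["k1"], p.get("Q2", 0.0), p.get("k2", 0.0))
        if self.model == "bulgakov":
            return ("bulgakov_approx", p["A_B"], p["lambda_d"])
        raise ValidationError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class BacktestResult:
    """Blind-test outcome: fit on the early window, score on the late one."""

    split_day: float
    train: FitResult
    epsilon2_test: float
    n_test: int


def epsilon2(series: ConcentrationSeries, predicted) -> float:
    """Squared relative error between a series and model values.

    sum_i ((C_m_i - C(t_i)) / C_m_i)^2 over aligned points.
    """
    pred = np.asarray(predicted, dtype=float)
    meas = series.values
    if pred.shape != meas.shape:
        raise ValidationError(
            f"length mismatch: {meas.size} measurements vs {pred.size} predictions"
        )
    r = (meas - pred) / meas
    return float(np.dot(r, r))


# ----------------------------------------------------------------------
# internal parametrisations
# ----------------------------------------------------------------------

_ALPHA_BOUNDS = (0.01, 0.99)


def _alpha_to_u(alpha: float, lo: float, hi: float) -> float:
    x = (alpha - lo) / (hi - lo)
    x = min(max(x, 1e-12), 1.0 - 1e-12)
    return float(special.logit(x))


def _u_to_alpha(u: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * float(special.expit(u))


_Y_HALF_CACHE: dict = {}


def _y_half(alpha: float, settings: MLSettings) -> float:
    """Argument y at which E_alpha(-y) = 1/2, used to seed theta."""
    from .mittag_leffler import ml_neg

    key = round(alpha, 6)
    if key not in _Y_HALF_CACHE:
        _Y_HALF_CACHE[key] = optimize.brentq(
            lambda y: ml_neg(alpha, y, settings) - 0.5, 1e-6, 50.0
        )
    return _Y_HALF_CACHE[key]


def _loglinear(t: np.ndarray, v: np.ndarray):
    """Least-squares line through (t, log v); returns (amplitude, rate)."""
    slope, intercept = np.polyfit(t, np.log(v), 1)
    return math.exp(intercept), max(-slope, 1e-12)


def _default_init(series: ConcentrationSeries, model: str, lambda_d: float,
                  settings: MLSettings) -> dict:
    t, v = series.t_days, series.values
    if model == "fdm":
        alpha0 = 0.5
        t_mid = 0.5 * (t[0] + t[-1])
        theta0 = _y_half(alpha0, settings) / max(t_mid, 1.0) ** alpha0
        return {"A": float(v[0]), "alpha": alpha0, "theta": theta0}
    if model == "tdm":
        n = len(t)
        lo, hi = t[: max(n // 2, 2)], t[n // 2:]
        vlo, vhi = v[: max(n // 2, 2)], v[n // 2:]
        Q2, k2 = _loglinear(hi, vhi)
        resid = vlo - Q2 * np.exp(-k2 * lo)
        pos = resid > 0
        if pos.sum() >= 2:
            Q1, k1 = _loglinear(lo[pos], resid[pos])
        else:
            Q1, k1 = float(v[0]) * 0.5, 5.0 / max(t[0], 1.0)
        k1 = max(k1, k2 * 1.5 + 1e-9)
        return {"Q1": Q1, "k1": k1, "Q2": Q2, "k2": k2}
    if model == "sdm":
        Q, k = _loglinear(t, v)
        return {"Q1": Q, "k1": k}
    if model == "bulgakov":
        A_B = float(np.median(v * np.sqrt(t) * np.exp(lambda_d * t)))
        return {"A_B": A_B}
    raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")


_N_FREE = {"fdm": 3, "tdm": 4, "sdm": 2, "bulgakov": 1}


def fit_model(
    series: ConcentrationSeries,
    model: str,
    init: Optional[dict] = None,
    bounds: Optional[dict] = None,
    fixed: Optional[dict] = None,
    settings: MLSettings = DEFAULT_SETTINGS,
    max_nfev: int = 4000,
) -> FitResult:
    """Fit one prediction model to a concentration series.

    Parameters
    ----------
    series : ConcentrationSeries
        Measurements; at least one more point than free parameters.
    model : {"fdm", "tdm", "sdm", "bulgakov"}
        Model family.  "bulgakov" fits the one-parameter large-time
        approximation A_B t^(-1/2) e^(-lambda_d t).
    init : dict, optional
        Starting values in canonical parameter names; defaults are
        derived from the data (first value for amplitudes, log-linear
        segment fits for decay rates, alpha = 0.5).
    bounds : dict, optional
        Currently supports ``{"alpha": (lo, hi)}`` overriding the
        default (0.01, 0.99) box for the FDM exponent.
    fixed : dict, optional
        ``lambda_d`` (decay constant, default 137Cs); ``tau``
        (reporting convention: if given, the fitted theta is also
        expressed as xi = theta * tau^alpha in the result); for the
        FDM, ``A`` may be fixed to a known initial concentration, which
        restores identifiability of (alpha, theta) on windows that
        start long after the release (A and theta are otherwise only
        jointly constrained once the curve is in its power-law regime).
    settings : MLSettings
        Mittag-Leffler evaluation settings for the FDM.
    max_nfev : int
        Levenberg-Marquardt residual-evaluation budget.

    Returns
    -------
    FitResult
        Never raises on non-convergence: ``converged`` is False and the
        diagnostics describe the failure.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    n_free = _N_FREE[model]
    if len(series) <= n_free:
        raise ValidationError(
            f"{model} has {n_free} free parameters; need more than "
            f"{n_free} points, got {len(series)}"
        )
    fixed = dict(fixed or {})
    lambda_d = float(fixed.get("lambda_d", CS137_LAMBDA_D))
    tau_conv = fixed.get("tau")
    alo, ahi = (bounds or {}).get("alpha", _ALPHA_BOUNDS)
    p0 = _default_init(series, model, lambda_d, settings)
    if init:
        p0.update(init)

    t, meas = series.t_days, series.values

    if model == "fdm":
        a0 = min(max(p0["alpha"], alo + 1e-6), ahi - 1e-6)
        A_fixed = fixed.get("A")
        if A_fixed is not None:
            if not A_fixed > 0:
                raise ValidationError("fixed A must be positive")
            x0 = [_alpha_to_u(a0, alo, ahi), math.log(p0["theta"])]

            def unpack(x):
                return FDMParams(
                    A=float(A_fixed),
                    alpha=_u_to_alpha(x[0], alo, ahi),
                    theta=math.exp(x[1]),
                    lambda_d=lambda_d,
                )

        else:
            x0 = [math.log(p0["A"]), _alpha_to_u(a0, alo, ahi), math.log(p0["theta"])]

            def unpack(x):
                return FDMParams(
                    A=math.exp(x[0]),
                    alpha=_u_to_alpha(x[1], alo, ahi),
                    theta=math.exp(x[2]),
                    lambda_d=lambda_d,
                )

        def curve(x):
            return c_fdm(t, unpack(x), settings)

    elif model in ("tdm", "sdm"):
        if model == "tdm":
            x0 = [math.log(max(p0[k], 1e-12)) for k in ("Q1", "k1", "Q2", "k2")]

            def curve(x):
                q1, k1, q2, k2 = np.exp(x)
                return q1 * np.exp(-k1 * t) + q2 * np.exp(-k2 * t)

            def unpack(x):
                q1, k1, q2, k2 = np.exp(x)
                return TDMParams.ordered(q1, k1, q2, k2)

        else:
            x0 = [math.log(max(p0[k], 1e-12)) for k in ("Q1", "k1")]

            def curve(x):
                q1, k1 = np.exp(x)
                return q1 * np.exp(-k1 * t)

            def unpack(x):
                q1, k1 = np.exp(x)
                return TDMParams(Q1=q1, k1=k1)

    else:  # bulgakov approximate form
        if np.any(t <= 0):
            raise ValidationError("bulgakov approximate form requires t > 0")
        x0 = [math.log(p0["A_B"])]

        def curve(x):
            return c_bulgakov_approx(t, math.exp(x[0]), lambda_d)

        def unpack(x):
            return math.exp(x[0])

    def residuals(x):
        return (meas - curve(x)) / meas

    # Multi-start over the anomalous-diffusion exponent: the relative
    # objective has ridge-shaped level sets in (alpha, theta, A) and a
    # single start can settle in a distant ridge minimum.
    starts = [list(x0)]
    if model == "fdm" and not (init and "alpha" in init):
        t_mid = 0.5 * (t[0] + t[-1])
        a_slot = 0 if fixed.get("A") is not None else 1
        for a_try in (0.3, 0.8):
            alt = list(x0)
            alt[a_slot] = _alpha_to_u(min(max(a_try, alo + 1e-6), ahi - 1e-6), alo, ahi)
            if not (init and "theta" in init):
                alt[a_slot + 1] = math.log(
                    _y_half(a_try, settings) / max(t_mid, 1.0) ** a_try
                )
            starts.append(alt)

    res = None
    for x_start in starts:
        trial = optimize.least_squares(
            residuals,
            x_start,
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=max_nfev,
        )
        if res is None or trial.cost < res.cost:
            res = trial
    eps2 = float(2.0 * res.cost)
    grad_norm = float(np.max(np.abs(res.grad))) if res.grad is not None else math.nan
    converged = res.status > 0

    at_bound = False
    if model == "fdm":
        fitted = unpack(res.x)
        alpha_hat = fitted.alpha
        margin = 0.02 * (ahi - alo)
        at_bound = alpha_hat <= alo + margin or alpha_hat >= ahi - margin
        params = {
            "A": fitted.A,
            "alpha": alpha_hat,
            "theta": fitted.theta,
            "lambda_d": lambda_d,
        }
        if tau_conv is not None:
            params["tau"] = float(tau_conv)
            params["xi"] = fitted.xi_for_tau(float(tau_conv))
    elif model in ("tdm", "sdm"):
        fitted = unpack(res.x)
        params = {"Q1": fitted.Q1, "k1": fitted.k1, "Q2": fitted.Q2, "k2": fitted.k2}
    else:
        params = {"A_B": unpack(res.x), "lambda_d": lambda_d}

    return FitResult(
        model=model,
        params=params,
        epsilon2=eps2,
        n_points=len(series),
        converged=converged,
        n_iterations=int(res.nfev),
        grad_norm=grad_norm,
        at_bound=at_bound,
        message=str(res.message),
    )


def backtest(
    series: ConcentrationSeries,
    split_day: float,
    model: str,
    **fit_kwargs,
) -> BacktestResult:
    """Blind test: fit on t <= split_day, score eps^2 on t > split_day.

    The train window includes the split day itself; parameters are
    frozen before the held-out evaluation.
    """
    t = series.t_days
    train_mask = t <= split_day
    test_mask = ~train_mask
    if not train_mask.any() or not test_mask.any():
        raise ValidationError(
            f"split day {split_day} must fall strictly inside the sampled "
            f"range [{t[0]}, {t[-1]}]"
        )
    train = series.restrict(train_mask)
    test = series.restrict(test_mask)
    fit = fit_model(train, model, **fit_kwargs)
    settings = fit_kwargs.get("settings", DEFAULT_SETTINGS)
    pred = predict(fit.to_params(), test.t_days, settings=settings)
    return BacktestResult(
        split_day=float(split_day),
        train=fit,
        epsilon2_test=epsilon2(test, pred),
        n_test=len(test),
    )


def predict(params, t_grid, settings: MLSettings = DEFAULT_SETTINGS) -> np.ndarray:
    """Evaluate a fitted model on a time grid (days, non-negative)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise DomainError("prediction times must be non-negative")
    if isinstance(params, FDMParams):
        return np.asarray(c_fdm(t_grid, params, settings))
    if isinstance(params, TDMParams):
        return np.asarray(c_tdm(t_grid, params))
    if isinstance(params, BulgakovParams):
        return np.asarray(c_bulgakov_full(t_grid, params))
    if isinstance(params, tuple) and params and params[0] == "bulgakov_approx":
        _, A_B, lam = params
        return np.asarray(c_bulgakov_approx(t_grid, A_B, lam))
    raise ValidationError(f"unsupported parameter object {type(params).__name__}")


def correlate_media(
    water: ConcentrationSeries,
    fish: ConcentrationSeries,
    pairing_window: float = 30.0,
) -> float:
    """Pearson correlation between paired water and fish concentrations.

    Points are paired greedily by nearest sampling time, each point used
    at most once, within +/- ``pairing_window`` days.  At least three
    pairs are required.
    """
    if pairing_window < 0:
        raise ValidationError("pairing window must be non-negative")
    dt = np.abs(water.t_days[:, None] - fish.t_days[None, :])
    ii, jj = np.nonzero(dt <= pairing_window)
    order = np.argsort(dt[ii, jj], kind="stable")
    used_w = np.zeros(len(water), dtype=bool)
    used_f = np.zeros(len(fish), dtype=bool)
    pairs = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_w[i] and not used_f[j]:
            used_w[i] = used_f[j] = True
            pairs.append((i, j))
    if len(pairs) < 3:
        raise ValidationError(
            f"need at least 3 pairable points within +/-{pairing_window} days, "
            f"got {len(pairs)}"
        )
    iw, jf = map(np.array, zip(*pairs))
    r = stats.pearsonr(water.values[iw], fish.values[jf]).statistic
    return float(r)
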