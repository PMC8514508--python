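"""Synthetic concentration series with the statistical structure the
analysis assumes.

The measured Lake Onuma tables live in an external supplement and are
not redistributable, so fixtures are generated: a forward model (FDM or
TDM) truth curve, sampled at irregular or regular days inside the
monitored window, perturbed by multiplicative lognormal noise

    C_i = model(t_i) * exp(eps_i),   eps_i ~ N(0, noise_sd_rel^2) i.i.d.

Multiplicative noise is the error model under which the squared
relative error is the natural fitting objective, and it keeps every
generated value strictly positive.  The default design mirrors the
study conditions: 40 points uniformly spaced over days 234-1981 after
the release, FDM truth with A = 1256 Bq m^-3, alpha = 0.62,
xi = 5.00, tau = 693 d, 137Cs decay, and 10% relative noise.

A paired fish series can be derived from a water series through a
proportionality factor with its own lognormal noise, emulating the
observed tight water-fish coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .fitting import ConcentrationSeries
from .mittag_leffler import DEFAULT_SETTINGS, MLSettings
from .models import FDMParams, TDMParams, c_fdm, c_tdm

__all__ = ["SyntheticSpec", "default_fdm_truth", "generate_series", "generate_paired_fish"]


def default_fdm_truth() -> FDMParams:
    """FDM truth used by the default fixtures (lake-water conditions)."""
    return FDMParams.from_xi_tau(A=1256.0, alpha=0.62, xi=5.00, tau=693.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe for one fixture series.

    Either ``sampling_days`` gives the days explicitly, or the
    (n_points, day_min, day_max, spacing) design generates them;
    spacing is "uniform" or "log".
    """

    params: Union[FDMParams, TDMParams] = field(default_factory=default_fdm_truth)
    n_points: int = 40
    day_min: float = 234.0
    day_max: float = 1981.0
    spacing: str = "uniform"
    sampling_days: Optional[Sequence[float]] = None
    noise_sd_rel: float = 0.10
    medium: str = "water"
    seed: int = 0
    ml_settings: MLSettings = field(default_factory=lambda: DEFAULT_SETTINGS)

    def __post_init__(self) -> None:
        if self.sampling_days is None:
            if self.n_points < 5:
                raise ValidationError("need at least 5 sampling points")
            if self.day_min < 0 or self.day_max <= self.day_min:
                raise ValidationError("require 0 <= day_min < day_max")
            if self.spacing not in ("uniform", "log"):
                raise ValidationError("spacing must be 'uniform' or 'log'")
        if self.noise_sd_rel < 0:
            raise ValidationError("noise_sd_rel must be non-negative")

    def days(self) -> np.ndarray:
        if self.sampling_days is not None:
            d = np.asarray(self.sampling_days, dtype=float)
            if d.size < 5:
                raise ValidationError("need at least 5 sampling points")
            return d
        if self.spacing == "log":
            return np.geomspace(max(self.day_min, 1e-6), self.day_max, self.n_points)
        return np.linspace(self.day_min, self.day_max, self.n_points)


def _truth_curve(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    if isinstance(spec.params, FDMParams):
        return np.asarray(c_fdm(t, spec.params, spec.ml_settings))
    if isinstance(spec.params, TDMParams):
        return np.asarray(c_tdm(t, spec.params))
    raise ValidationError(f"unsupported model params {type(spec.params).__name__}")


def generate_series(spec: SyntheticSpec) -> ConcentrationSeries:
    """Generate one fixture series; deterministic given the spec's seed."""
    t = spec.days()
    truth = _truth_curve(spec, t)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd_rel, size=t.size) if spec.noise_sd_rel else 0.0
    values = truth * np.exp(noise)
    return ConcentrationSeries(t_days=t, values=values, medium=spec.medium)


def generate_paired_fish(
    water: ConcentrationSeries,
    proportionality: float,
    noise_sd_rel: float,
    seed: int = 0,
) -> ConcentrationSeries:
    """Fish series proportional to a water series with lognormal noise.

    fish_i = proportionality * water_i * exp(eps_i) at the same sampling
    days; the unit changes to Bq kg^-1 wet weight.
    """
    if not proportionality > 0:
        raise ValidationError("proportionality must be positive")
    if noise_sd_rel < 0:
        raise ValidationError("noise_sd_rel must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_rel, size=len(water)) if noise_sd_rel else 0.0
    values = proportionality * water.values * np.exp(noise)
    return ConcentrationSeries(
        t_days=water.t_days, values=values, medium="fish", origin_date=water.origin_date
    )
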