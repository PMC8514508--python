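"""File formats and run configuration.

Concentration series travel as plain CSV with header ``day,value``
(optionally ``medium``): day is a float number of days since the
release (day 0 = 2011-03-15 for the Fukushima fixtures, fractional days
allowed), value a strictly positive activity concentration.  Fit
results are written as JSON reports carrying the canonical parameters,
the squared relative error, a convergence block, the software version
and a hash of the configuration that produced them, so every run is
reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .fitting import ConcentrationSeries, FitResult
from .mittag_leffler import MLSettings
from .models import CS137_HALF_LIFE_DAYS

__all__ = [
    "RunConfig",
    "read_series_csv",
    "write_series_csv",
    "write_curve_csv",
    "write_fit_report",
    "read_fit_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings shared across pipeline commands.

    half_life_days sets lambda_d (137Cs by default and echoed in every
    report — no silent defaults); tau_convention, when set, is the
    fixed tau at which a fitted FDM theta is also reported as xi.
    """

    half_life_days: float = CS137_HALF_LIFE_DAYS
    ml: MLSettings = field(default_factory=MLSettings)
    max_nfev: int = 4000
    alpha_bounds: tuple = (0.01, 0.99)
    tau_convention: Optional[float] = None
    pairing_window_days: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValidationError("half_life_days must be positive")
        lo, hi = self.alpha_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("alpha_bounds must satisfy 0 < lo < hi < 1")

    def hash(self) -> str:
        """Stable hex digest of the configuration (first 12 chars)."""
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key=value (or YAML mapping) file."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a flat mapping")
        ml_keys = {f.name for f in dataclasses.fields(MLSettings)}
        ml_kwargs = {k: raw.pop(k) for k in list(raw) if k in ml_keys}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "alpha_bounds" in raw:
            raw["alpha_bounds"] = tuple(raw["alpha_bounds"])
        kwargs = dict(raw)
        if ml_kwargs:
            kwargs["ml"] = MLSettings(**ml_kwargs)
        return cls(**kwargs)


def read_series_csv(path) -> ConcentrationSeries:
    """Read a concentration series from CSV with header ``day,value[,medium]``.

    Rows are sorted by day; duplicate days, missing columns,
    non-numeric cells and non-positive values are rejected with the
    offending row named.  Non-positive values are unusable because the
    relative-error objective divides by the measured concentration.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"day", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    for col in ("day", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(
                f"{path}: non-numeric or missing {col!r} in data row {row + 1}"
            )
        df[col] = coerced
    nonpos = df["value"] <= 0
    if nonpos.any():
        row = int(np.nonzero(nonpos.to_numpy())[0][0])
        raise ValidationError(
            f"{path}: non-positive value in data row {row + 1}; the squared "
            "relative error divides by each measured concentration"
        )
    if df["day"].duplicated().any():
        dup = df.loc[df["day"].duplicated(), "day"].iloc[0]
        raise ValidationError(f"{path}: duplicate sampling day {dup}")
    df = df.sort_values("day", kind="stable")
    medium = "water"
    if "medium" in df.columns:
        media = set(df["medium"].astype(str))
        if len(media) > 1:
            raise ValidationError(f"{path}: mixed media {sorted(media)} in one series")
        medium = media.pop()
    return ConcentrationSeries(
        t_days=df["day"].to_numpy(float),
        values=df["value"].to_numpy(float),
        medium=medium,
    )


def write_series_csv(series: ConcentrationSeries, path) -> None:
    """Write a series as CSV at full float precision (lossless round trip)."""
    # no float_format: pandas writes shortest round-trip repr
    df = pd.DataFrame(
        {"day": series.t_days, "value": series.values, "medium": series.medium}
    )
    df.to_csv(path, index=False)


def write_curve_csv(t_days, values, path) -> None:
    """Write an evaluated model curve as CSV with columns day,value."""
    pd.DataFrame({"day": np.asarray(t_days), "value": np.asarray(values)}).to_csv(
        path, index=False, float_format=None
    )


def fit_report_dict(result: FitResult, config: Optional[RunConfig] = None) -> dict:
    config = config or RunConfig()
    return {
        "model": result.model,
        "params": {k: float(v) for k, v in result.params.items()},
        "epsilon2": result.epsilon2,
        "n_points": result.n_points,
        "convergence": {
            "converged": result.converged,
            "n_iterations": result.n_iterations,
            "grad_norm": result.grad_norm,
            "at_bound": result.at_bound,
            "message": result.message,
        },
        "half_life_days": config.half_life_days,
        "software_version": __version__,
        "config_hash": config.hash(),
    }


def write_fit_report(result: FitResult, path, config: Optional[RunConfig] = None) -> None:
    """Write a fit report as JSON (canonical params, eps^2, diagnostics)."""
    report = fit_report_dict(result, config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
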