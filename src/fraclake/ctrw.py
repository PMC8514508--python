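"""Continuous-time random walk (CTRW) Monte-Carlo validation.

The fractional-diffusion prediction formula rests on one microscopic
premise: a walker making Gaussian jumps separated by heavy-tailed
waiting times (tail exponent alpha in (0, 1)) subdiffuses, with mean
squared displacement growing like t^alpha instead of t.  This module
simulates that walk directly and estimates the MSD exponent, providing
an independent check of the premise without any transform algebra.

The waiting-time law is a shifted Pareto,

    w(t) = (alpha / tau) * (1 + t/tau)^(-(1+alpha)),

sampled by inverse CDF t = tau * (u^(-1/alpha) - 1).  Any law with this
power-law tail yields the same fractional-diffusion limit; tau is a
pure scale parameter (for 0 < alpha < 1 the mean waiting time
diverges).  Jump lengths are Gaussian with mean 0 and variance
2*sigma^2, matching the convention in which sigma^2 is half the second
moment of the jump-length distribution.

Walks are free-space (no boundaries): the clean, testable consequence
of the premise is unbounded subdiffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "CTRWConfig",
    "CTRWResult",
    "sample_waiting_times",
    "sample_jump_lengths",
    "simulate_msd",
]


@dataclass(frozen=True)
class CTRWConfig:
    """Configuration of one CTRW ensemble simulation.

    t_probes are the (strictly increasing) observation times in days;
    the MSD exponent is estimated by log-log regression over them, so
    they should span at least two decades well above tau_scale.
    """

    alpha: float
    tau_scale: float
    sigma: float
    n_particles: int
    t_probes: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.tau_scale > 0:
            raise DomainError("tau_scale must be positive")
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")
        if self.n_particles < 1:
            raise DomainError("n_particles must be at least 1")
        probes = np.asarray(self.t_probes, dtype=float)
        object.__setattr__(self, "t_probes", probes)
        if probes.ndim != 1 or probes.size < 2 or np.any(np.diff(probes) <= 0):
            raise ValidationError("t_probes must be strictly increasing, length >= 2")
        if probes[0] <= 0:
            raise ValidationError("t_probes must be positive")


@dataclass(frozen=True)
class CTRWResult:
    """Ensemble MSD at the probe times and the fitted growth exponent."""

    t_probes: np.ndarray
    msd: np.ndarray
    fitted_exponent: float
    stderr: float
    n_particles: int
    warning: str = ""


def sample_waiting_times(
    alpha: float, tau_scale: float, n: int, seed=0
) -> np.ndarray:
    """Draw n i.i.d. waiting times from the shifted-Pareto law.

    Inverse-CDF sampling: t = tau * (u^(-1/alpha) - 1) with u uniform
    on (0, 1]; u = 1 maps to t = 0.  ``seed`` may be an int or an
    existing numpy Generator.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if not tau_scale > 0:
        raise DomainError("tau_scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    u = 1.0 - u  # (0, 1] to keep the u=1 -> t=0 endpoint exact
    return tau_scale * (u ** (-1.0 / alpha) - 1.0)


def sample_jump_lengths(sigma: float, n: int, seed=0) -> np.ndarray:
    """Draw n Gaussian jump displacements, mean 0, variance 2*sigma^2."""
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, sigma * math.sqrt(2.0), size=n)


def simulate_msd(config: CTRWConfig) -> CTRWResult:
    """Simulate the CTRW ensemble and estimate the MSD growth exponent.

    Each particle alternates waiting times and instantaneous jumps until
    the last probe time; its squared displacement is recorded at every
    probe it passes.  The exponent is the slope of a log-log ordinary
    least-squares regression of MSD on time over all probes.

    The simulation is fully vectorised over particles and bit-for-bit
    reproducible for a given (config, seed).
    """
    probes = config.t_probes
    n_probes = probes.size
    t_max = probes[-1]
    span = probes[-1] / probes[0]
    warning = ""
    if span < 100.0:
        warning = (
            f"probe range spans only {math.log10(span):.2f} decades; "
            "at least 2 are recommended for a reliable exponent"
        )

    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    sum_x2 = np.zeros(n_probes)

    # active particle state, compacted as particles finish
    idx = np.arange(n)
    t_now = np.zeros(n)
    pos = np.zeros(n)
    next_probe = np.zeros(n, dtype=np.int64)

    while idx.size:
        m = idx.size
        w = sample_waiting_times(config.alpha, config.tau_scale, m, rng)
        t_new = t_now + w
        # record the pre-jump position at every probe inside [t_now, t_new)
        while True:
            rec = probes[np.minimum(next_probe, n_probes - 1)] < t_new
            rec &= next_probe < n_probes
            if not rec.any():
                break
            np.add.at(sum_x2, next_probe[rec], pos[rec] ** 2)
            next_probe[rec] += 1
        # jump happens at t_new
        pos = pos + sample_jump_lengths(config.sigma, m, rng)
        t_now = t_new
        alive = next_probe < n_probes
        if not alive.all():
            idx = idx[alive]
            t_now = t_now[alive]
            pos = pos[alive]
            next_probe = next_probe[alive]

    msd = sum_x2 / n
    with np.errstate(divide="ignore"):
        logt = np.log(probes)
        logm = np.log(msd)
    if not np.all(np.isfinite(logm)):
        # zero-jump degenerate case: MSD identically 0
        return CTRWResult(probes, msd, math.nan, math.nan, n, warning or "MSD is zero")
    fit = stats.linregress(logt, logm)
    return CTRWResult(
        t_probes=probes,
        msd=msd,
        fitted_exponent=float(fit.slope),
        stderr=float(fit.stderr),
        n_particles=n,
        warning=warning,
    )
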