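"""Emission distributions: circular angle laws and Gamma step lengths.

Angles follow a von-Mises distribution (circular analogue of the normal,
mean direction ``mu``, concentration ``kappa >= 0``) or, alternatively, a
wrapped Cauchy (mean direction ``mu``, concentration ``rho in [0, 1)``).
Zero concentration gives the uniform circular density in either family.

Step lengths follow a Gamma distribution parameterized by its expectation
``mu_gamma`` and standard deviation ``sigma_gamma`` — the parameterization
movement analysts report — converted internally to shape/scale:
``shape = (mu/sigma)^2``, ``scale = sigma^2/mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "VON_MISES",
    "WRAPPED_CAUCHY",
    "AngleDist",
    "StepDist",
    "angle_logpdf",
    "angle_sample",
    "step_logpdf",
    "step_sample",
]

VON_MISES = "vonmises"
WRAPPED_CAUCHY = "wrappedcauchy"
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class AngleDist:
    """Circular emission law for one hidden state."""

    mu: float
    kappa: float
    family: str = VON_MISES

    def __post_init__(self):
        if self.family not in (VON_MISES, WRAPPED_CAUCHY):
            raise ValueError(f"unknown angle family {self.family!r}")
        if self.kappa < 0:
            raise ValueError("concentration must be non-negative")
        if self.family == WRAPPED_CAUCHY and not self.kappa < 1.0:
            raise ValueError("wrapped-Cauchy concentration rho must be in [0, 1)")


@dataclass(frozen=True)
class StepDist:
    """Gamma step-length law in (mean, sd) parameterization."""

    mu_gamma: float
    sigma_gamma: float

    def __post_init__(self):
        if self.mu_gamma <= 0 or self.sigma_gamma <= 0:
            raise ValueError("Gamma mean and sd must be positive")

    @property
    def shape(self) -> float:
        return (self.mu_gamma / self.sigma_gamma) ** 2

    @property
    def scale(self) -> float:
        return self.sigma_gamma**2 / self.mu_gamma


def angle_logpdf(theta, dist: AngleDist):
    """Log density of ``theta`` under ``dist``; NaN inputs give NaN."""
    theta = np.asarray(theta, dtype=float)
    if dist.family == VON_MISES:
        out = dist.kappa * np.cos(theta - dist.mu) - _LOG_2PI - np.log(
            special.i0e(dist.kappa)
        ) - dist.kappa
    else:
        rho = dist.kappa
        out = (
            np.log1p(-(rho**2))
            - _LOG_2PI
            - np.log1p(rho**2 - 2.0 * rho * np.cos(theta - dist.mu))
        )
    return out if out.ndim else float(out)


def step_logpdf(s, dist: StepDist):
    """Gamma log density of step length ``s``; non-positive ``s`` gives -inf."""
    s = np.asarray(s, dtype=float)
    k, scale = dist.shape, dist.scale
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            s > 0,
            (k - 1.0) * np.log(s) - s / scale - special.gammaln(k) - k * np.log(scale),
            -np.inf,
        )
    return out if out.ndim else float(out)


def angle_sample(dist: AngleDist, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` angles in ``(-pi, pi]``, reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.family == VON_MISES:
        draws = rng.vonmises(dist.mu, dist.kappa, size=n)
    else:
        if dist.kappa == 0.0:
            draws = rng.uniform(-np.pi, np.pi, size=n)
        else:
            draws = stats.wrapcauchy.rvs(
                dist.kappa, loc=dist.mu, size=n, random_state=rng
            )
    from .geometry import wrap_angle

    return np.atleast_1d(wrap_angle(draws))


def step_sample(dist: StepDist, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` Gamma step lengths, reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=dist.shape, scale=dist.scale, size=n)
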