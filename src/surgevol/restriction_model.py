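"""Gamma restriction-rate distributions and the three analysis scenarios.

Each restriction state maps a hospital's reference weekly caseload to an
actual caseload through a multiplicative rate drawn from a state-specific
gamma distribution, parameterized by a target median (or mean) and a shared
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

#: Target restriction levels per state, by scenario.
SCENARIO_LEVELS: dict[str, tuple[float, float, float, float]] = {
    "baseline": (1.0, 0.7, 0.4, 0.1),
    "optimistic": (1.0, 0.8, 0.5, 0.25),
    "pessimistic": (1.0, 0.5, 0.3, 0.03),
}

DEFAULT_VARIANCE = 0.005


@dataclass(frozen=True)
class GammaParams:
    """Shape/rate parameterization; density ~ x^(shape-1) exp(-rate x)."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    @property
    def median(self) -> float:
        return float(gamma_dist.ppf(0.5, a=self.shape, scale=1.0 / self.rate))

    def rvs(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


def _median_given_rate(rate: float, variance: float) -> float:
    # with shape = variance * rate^2 the variance constraint holds exactly
    return float(gamma_dist.ppf(0.5, a=variance * rate**2, scale=1.0 / rate))


def solve_gamma_params(median: float, variance: float) -> GammaParams:
    """Find (shape, rate) with the requested median and variance.

    The variance constraint is imposed exactly through
    ``shape = variance * rate**2``; the rate is then found by bracketed
    one-dimensional root finding on the median, which is strictly
    increasing in the rate under that substitution.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if variance <= 0:
        raise ValueError("variance must be positive")

    def f(rate: float) -> float:
        return _median_given_rate(rate, variance) - median

    # the mean is variance * rate and median < mean for a gamma, so
    # rate = median / variance is always a lower bracket endpoint
    lo = median / variance
    hi = lo * 2
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2
    else:  # pragma: no cover - unreachable for positive inputs
        raise RuntimeError("failed to bracket the gamma rate")
    rate = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    params = GammaParams(shape=variance * rate**2, rate=rate)
    assert abs(params.median - median) <= 1e-9
    return params


def gamma_params_from_mean(mean: float, variance: float) -> GammaParams:
    """Moment-matching alternative: interpret the level as the mean."""
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be positive")
    return GammaParams(shape=mean**2 / variance, rate=mean / variance)


@dataclass(frozen=True)
class RestrictionScenario:
    """Four per-state restriction-rate distributions under one scenario."""

    name: str
    levels: tuple[float, float, float, float]
    variance: float
    params: tuple[GammaParams, GammaParams, GammaParams, GammaParams]
    level_kind: str = "median"

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.params])

    @property
    def shapes(self) -> np.ndarray:
        return np.array([p.shape for p in self.params])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.rate for p in self.params])


def build_scenario(name: str, variance: float = DEFAULT_VARIANCE,
                   levels=None, level_kind: str = "median") -> RestrictionScenario:
    """Assemble a named or custom scenario.

    ``level_kind`` selects whether the per-state levels are matched as
    medians (default) or means of the gamma distributions.
    """
    if levels is None:
        try:
            levels = SCENARIO_LEVELS[name]
        except KeyError:
            raise ValueError(
                f"unknown scenario {name!r}; known: {sorted(SCENARIO_LEVELS)} "
                f"(or pass custom levels)") from None
    levels = tuple(float(v) for v in levels)
    if len(levels) != 4:
        raise ValueError("a scenario needs exactly 4 levels")
    if any(a <= b for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly decreasing across states")
    if level_kind == "median":
        params = tuple(solve_gamma_params(v, variance) for v in levels)
    elif level_kind == "mean":
        params = tuple(gamma_params_from_mean(v, variance) for v in levels)
    else:
        raise ValueError("level_kind must be 'median' or 'mean'")
    return RestrictionScenario(name=name, levels=levels, variance=variance,
                               params=params, level_kind=level_kind)
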