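"""Seeded synthetic fixtures with the statistical structure the pipeline
assumes: a latent banded Markov chain observed through multinomial polls, a
right-skewed hospital registry, and a noisy external reference series.

The latent truth (weekly proportions, transition matrices) is always kept
alongside the observations so that recovery experiments can measure
estimation error.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_tables import (DEFAULT_BASELINE, WEEKS_PER_YEAR, HospitalRegistry,
                        PollSeries, ReferenceSeries, write_poll_series,
                        write_reference_series, write_registry)
from .transition_estimation import (FREE_ENTRIES, TransitionChain,
                                    TransitionMatrix)

FIRST_POLL_DATE = dt.date(2020, 3, 13)

#: Entries of each row allowed by the band (including the diagonal).
_ROW_SUPPORT = tuple(
    tuple(j for i, j in FREE_ENTRIES if i == row) for row in range(4))


@dataclass
class SyntheticConfig:
    n_weeks: int = 17
    n_hospitals: int = 1989
    weekly_baseline_total: float = 44500.0
    sample_size_range: tuple[int, int] = (47, 288)
    volatility: float = 0.3
    min_annual: int = 100
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        lo, hi = self.sample_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("sample_size_range must be positive and ordered")
        if self.volatility < 0:
            raise ValueError("volatility must be non-negative")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent substream keyed by integers, all rooted at seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


def make_transition_chain(config: SyntheticConfig,
                          rng: np.random.Generator | None = None) -> TransitionChain:
    """Random banded row-stochastic matrices near the identity.

    Each row is the identity row plus uniform perturbations of size
    ``volatility`` on its banded support, re-normalized; volatility 0 gives
    exactly the identity every week.
    """
    rng = config.rng(1) if rng is None else rng
    matrices = []
    for _ in range(config.n_weeks - 1):
        m = np.eye(4)
        for i, support in enumerate(_ROW_SUPPORT):
            m[i, list(support)] += config.volatility * rng.uniform(
                0.0, 1.0, size=len(support))
            m[i] /= m[i].sum()
        matrices.append(TransitionMatrix(m))
    return TransitionChain(matrices=matrices)


def latent_proportions(chain: TransitionChain, n_weeks: int,
                       baseline=None) -> np.ndarray:
    """Forward-propagate the baseline through the chain.

    Returns (n_weeks, 4): week t's true proportions.  The transition into
    week 1 reuses the first matrix (each weekly matrix governs the
    transitions both into and out of its week, matching the estimator's
    two-step windows); the remaining transitions use matrices in order.
    """
    y = DEFAULT_BASELINE.copy() if baseline is None else \
        np.asarray(baseline, dtype=float)
    out = []
    for t in range(n_weeks):
        y = y @ chain.matrices[min(max(t - 1, 0), len(chain) - 1)].values
        out.append(y)
    return np.vstack(out)


def simulate_polls(chain: TransitionChain, config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> PollSeries:
    """Observe the latent chain through weekly multinomial polls.

    Sample sizes are uniform over ``sample_size_range``; the latent truth is
    attached to the returned series.
    """
    if len(chain) != config.n_weeks - 1:
        raise ValueError("chain length must be n_weeks - 1")
    rng = config.rng(2) if rng is None else rng
    truth = latent_proportions(chain, config.n_weeks)
    lo, hi = config.sample_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_weeks)
    counts = np.vstack([rng.multinomial(n, p) for n, p in zip(sizes, truth)])
    dates = [FIRST_POLL_DATE + dt.timedelta(weeks=t)
             for t in range(config.n_weeks)]
    return PollSeries(dates=dates, proportions=counts / sizes[:, None],
                      counts=counts, latent=truth)


def make_registry(config: SyntheticConfig,
                  rng: np.random.Generator | None = None) -> HospitalRegistry:
    """Right-skewed annual caseloads summing to the target weekly baseline.

    Counts are ``min_annual`` plus a rescaled log-normal excess, so the
    eligibility floor holds for every hospital and the summed weekly
    reference equals ``weekly_baseline_total`` exactly.
    """
    rng = config.rng(3) if rng is None else rng
    n = config.n_hospitals
    total_annual = config.weekly_baseline_total * WEEKS_PER_YEAR
    floor_total = config.min_annual * n
    if total_annual <= floor_total:
        raise ValueError("weekly_baseline_total too small for the minimum "
                         "annual count at this registry size")
    excess = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)
    annual = config.min_annual + excess * (total_annual - floor_total) / excess.sum()
    return HospitalRegistry(
        hospital_id=[f"H{i:05d}" for i in range(n)], annual_count=annual)


def make_reference_series(estimates, noise_sd: float, seed: int,
                          date_offset_days: int = 0) -> ReferenceSeries:
    """A noisy stand-in external series derived from an estimate series.

    Estimate percent-of-baseline values are linearly interpolated at dates
    shifted by ``date_offset_days`` (shifted dates falling outside the
    estimate range are dropped) and perturbed with Gaussian noise.
    """
    from .comparison import interpolate_to_dates

    if len(estimates.dates) == 0:
        raise ValueError("estimates must be non-empty")
    rng = np.random.default_rng(seed)
    shifted = [d + dt.timedelta(days=date_offset_days) for d in estimates.dates]
    lo, hi = estimates.dates[0], estimates.dates[-1]
    kept = [d for d in shifted if lo <= d <= hi]
    values = interpolate_to_dates(estimates.dates,
                                  estimates.percent_of_baseline, kept)
    values = values + rng.normal(0.0, noise_sd, size=len(kept))
    return ReferenceSeries(dates=kept, percent=np.maximum(values, 0.0))


@dataclass
class FixtureSet:
    """A complete synthetic input set plus its generating truth."""

    polls: PollSeries
    registry: HospitalRegistry
    chain: TransitionChain
    config: SyntheticConfig
    reference: ReferenceSeries | None = None


def make_fixture_set(config: SyntheticConfig) -> FixtureSet:
    chain = make_transition_chain(config)
    polls = simulate_polls(chain, config)
    chain.dates = list(polls.dates)
    registry = make_registry(config)
    return FixtureSet(polls=polls, registry=registry, chain=chain,
                      config=config)


def write_fixture_set(config: SyntheticConfig, out_dir,
                      reference_noise_sd: float = 3.0,
                      reference_offset_days: int = 3) -> FixtureSet:
    """Write polls.csv, registry.csv, reference.csv and truth.yaml.

    The reference series is derived from the noise-free expected volume
    trajectory under the baseline scenario so that the comparison stage has
    a correlated series to align against.
    """
    from .restriction_model import build_scenario
    from .volume_simulation import VolumeEstimateSeries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixture_set(config)
    truth = fx.polls.latent
    scenario = build_scenario("baseline")
    expected = truth @ scenario.means * fx.registry.total_weekly_reference
    expected_series = VolumeEstimateSeries(
        dates=fx.polls.dates, median=expected, ci_low=expected,
        ci_high=expected,
        percent_of_baseline=expected / fx.registry.total_weekly_reference * 100)
    fx.reference = make_reference_series(
        expected_series, noise_sd=reference_noise_sd,
        seed=config.seed + 4, date_offset_days=reference_offset_days)

    write_poll_series(fx.polls, out / "polls.csv")
    write_registry(fx.registry, out / "registry.csv")
    write_reference_series(fx.reference, out / "reference.csv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump({
            "config": {
                "n_weeks": config.n_weeks,
                "n_hospitals": config.n_hospitals,
                "weekly_baseline_total": config.weekly_baseline_total,
                "sample_size_range": list(config.sample_size_range),
                "volatility": config.volatility,
                "min_annual": config.min_annual,
                "lognormal_sigma": config.lognormal_sigma,
                "seed": config.seed,
            },
            "latent_proportions": truth.tolist(),
            "transition_matrices": [m.values.tolist() for m in fx.chain.matrices],
        }, fh, sort_keys=False)
    return fx
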