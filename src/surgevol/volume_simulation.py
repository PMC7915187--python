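"""Monte Carlo simulation of weekly general-anesthesia volumes.

Each iteration allocates every hospital to a restriction state from the
first poll's distribution, evolves the states hospital-by-hospital through
the estimated weekly transition chain, draws a state-specific gamma
restriction rate per hospital-week, and sums reference-weighted volumes.
Weekly totals are summarized as medians with percentile confidence
intervals across iterations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .io_tables import HospitalRegistry
from .restriction_model import RestrictionScenario
from .transition_estimation import TransitionChain

DEFAULT_ITERATIONS = 1000
CI_PERCENTILES = (2.5, 97.5)


@dataclass
class SimulationRun:
    """Raw Monte Carlo output.

    ``weekly_totals`` has shape (iterations, n_weeks); ``states`` (kept only
    on request, shape (iterations, n_weeks, n_hospitals), 1-based labels in
    data terms but stored 0-based) allows transition audits.
    """

    weekly_totals: np.ndarray
    dates: list[dt.date] | None = None
    states: np.ndarray | None = None
    seed: int | None = None

    @property
    def iterations(self) -> int:
        return self.weekly_totals.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.weekly_totals.shape[1]


@dataclass
class VolumeEstimateSeries:
    """Per-week summary: median, 95% CI, and percent of the pre-period
    baseline (summed weekly reference volume)."""

    dates: list[dt.date]
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    percent_of_baseline: np.ndarray

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        self.percent_of_baseline = np.asarray(self.percent_of_baseline,
                                              dtype=float)
        n = len(self.dates)
        for name in ("median", "ci_low", "ci_high", "percent_of_baseline"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match dates")
        if np.any(self.ci_low > self.median + 1e-12) or \
                np.any(self.median > self.ci_high + 1e-12):
            raise ValueError("need ci_low <= median <= ci_high per week")

    def __len__(self) -> int:
        return len(self.dates)


def allocate_initial(registry: HospitalRegistry, y1,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw each hospital's initial state (0-based) independently from the
    first poll's distribution, irrespective of hospital size."""
    y1 = np.asarray(y1, dtype=float)
    if y1.shape != (4,) or abs(y1.sum() - 1) > 1e-6 or np.any(y1 < 0):
        raise ValueError("y1 must be a probability 4-vector")
    cum = np.cumsum(y1)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(len(registry)), side="right")


def evolve_states(initial: np.ndarray, chain: TransitionChain,
                  rng: np.random.Generator) -> np.ndarray:
    """Evolve hospital states through the chain.

    Returns shape (len(chain) + 1, n_hospitals): row 0 is the initial
    allocation, row t the states after applying matrix t-1.
    """
    states = np.empty((len(chain) + 1, len(initial)), dtype=np.int8)
    states[0] = initial
    for t, matrix in enumerate(chain.matrices):
        cum = np.cumsum(matrix.values, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(len(initial))
        rows = cum[states[t]]
        states[t + 1] = (u[:, None] >= rows).sum(axis=1)
    return states


def simulate_weekly_volumes(registry: HospitalRegistry, chain: TransitionChain,
                            y1, scenario: RestrictionScenario,
                            iterations: int = DEFAULT_ITERATIONS,
                            seed=None, reallocate: bool = True,
                            keep_states: bool = False) -> SimulationRun:
    """Run the Monte Carlo volume simulation.

    Per iteration: a fresh state allocation (unless ``reallocate`` is False,
    in which case one allocation drawn up front is shared by all
    iterations), a fresh trajectory through the chain, and fresh independent
    gamma restriction-rate draws per hospital-week.  Weekly volume is the
    sum over hospitals of weekly reference times drawn rate.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    n_weeks = len(chain) + 1
    weekly_ref = registry.weekly_reference
    shapes = scenario.shapes
    scales = 1.0 / scenario.rates
    totals = np.empty((iterations, n_weeks))
    kept = np.empty((iterations, n_weeks, len(registry)), dtype=np.int8) \
        if keep_states else None
    fixed_initial = None if reallocate else allocate_initial(registry, y1, rng)
    for it in range(iterations):
        initial = allocate_initial(registry, y1, rng) if reallocate \
            else fixed_initial
        states = evolve_states(initial, chain, rng)
        x = rng.gamma(shapes[states], scales[states])
        totals[it] = (weekly_ref[None, :] * x).sum(axis=1)
        if keep_states:
            kept[it] = states
    return SimulationRun(weekly_totals=totals, dates=chain.dates,
                         states=kept,
                         seed=seed if isinstance(seed, int) else None)


def summarize(run: SimulationRun, registry: HospitalRegistry) -> VolumeEstimateSeries:
    """Median and 2.5/97.5 percentiles per week across iterations.

    Percentiles use linear interpolation between order statistics (numpy's
    default convention).
    """
    if run.weekly_totals.size == 0:
        raise ValueError("empty simulation run")
    if run.dates is None:
        raise ValueError("simulation run carries no dates")
    med = np.median(run.weekly_totals, axis=0)
    lo, hi = np.percentile(run.weekly_totals, CI_PERCENTILES, axis=0)
    baseline = registry.total_weekly_reference
    return VolumeEstimateSeries(
        dates=list(run.dates), median=med, ci_low=lo, ci_high=hi,
        percent_of_baseline=med / baseline * 100.0)
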