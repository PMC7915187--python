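"""Input/output tables: poll series, hospital registry, reference series, estimates.

These readers define the on-disk contract of the pipeline.  All tables are
plain CSV; see the dialect notes on each reader.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_CATEGORIES = 4

#: Row sums of percentage-rounded proportion tables are accepted in this
#: interval (values rounded to one decimal in percent can drift by ~1.5%).
PROPORTION_SUM_RANGE = (0.985, 1.015)

DEFAULT_BASELINE = np.array([1.0, 0.0, 0.0, 0.0])

#: Weeks per year used to convert annual reference caseloads to weekly rates.
WEEKS_PER_YEAR = 52


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


def _as_dates(values) -> list[dt.date]:
    out = []
    for v in values:
        if isinstance(v, dt.datetime):
            out.append(v.date())
        elif isinstance(v, dt.date):
            out.append(v)
        else:
            out.append(dt.date.fromisoformat(str(v).strip()[:10]))
    return out


def _check_strictly_increasing(dates: list[dt.date], what: str) -> None:
    for a, b in zip(dates, dates[1:]):
        if b <= a:
            raise ValidationError(f"{what}: dates must be strictly increasing "
                                  f"({a} followed by {b})")


@dataclass
class PollSeries:
    """A dated sequence of 4-category response proportions.

    ``proportions[t]`` is the observed response distribution of poll ``t``
    (row-normalized).  ``counts`` is present when the series was built from
    raw response counts.  ``baseline`` is the assumed distribution before the
    first poll (everyone unrestricted by default).  ``latent`` optionally
    carries the true underlying proportions when the series is synthetic.
    """

    dates: list[dt.date]
    proportions: np.ndarray
    counts: np.ndarray | None = None
    baseline: np.ndarray = field(default_factory=lambda: DEFAULT_BASELINE.copy())
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = _as_dates(self.dates)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[1] != N_CATEGORIES:
            raise ValidationError("proportions must be a (T, 4) array")
        if len(self.dates) != self.proportions.shape[0]:
            raise ValidationError("dates and proportions lengths differ")
        _check_strictly_increasing(self.dates, "poll series")
        if np.any(self.proportions < 0):
            raise ValidationError("proportions must be non-negative")
        sums = self.proportions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("each proportions row must sum to 1 within 1e-6")
        self.proportions = self.proportions / sums[:, None]
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.proportions.shape:
                raise ValidationError("counts shape must match proportions")
            if np.any(self.counts < 0):
                raise ValidationError("counts must be non-negative")
        if self.baseline.shape != (N_CATEGORIES,) or abs(self.baseline.sum() - 1) > 1e-6:
            raise ValidationError("baseline must be a probability 4-vector")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class HospitalRegistry:
    """Hospitals with annual reference general-anesthesia caseloads."""

    hospital_id: list[str]
    annual_count: np.ndarray

    def __post_init__(self) -> None:
        self.hospital_id = [str(h) for h in self.hospital_id]
        self.annual_count = np.asarray(self.annual_count, dtype=float)
        if len(self.hospital_id) != len(self.annual_count):
            raise ValidationError("hospital_id and annual_count lengths differ")
        if len(set(self.hospital_id)) != len(self.hospital_id):
            raise ValidationError("hospital_id values must be unique")
        if np.any(self.annual_count < 0):
            raise ValidationError("annual counts must be non-negative")

    @property
    def weekly_reference(self) -> np.ndarray:
        return self.annual_count / WEEKS_PER_YEAR

    @property
    def total_weekly_reference(self) -> float:
        return float(self.weekly_reference.sum())

    def __len__(self) -> int:
        return len(self.hospital_id)


@dataclass
class ReferenceSeries:
    """External weekly percent-of-previous-year series used for validation."""

    dates: list[dt.date]
    percent: np.ndarray

    def __post_init__(self) -> None:
        self.dates = _as_dates(self.dates)
        self.percent = np.asarray(self.percent, dtype=float)
        if len(self.dates) != len(self.percent):
            raise ValidationError("dates and percent lengths differ")
        _check_strictly_increasing(self.dates, "reference series")
        if np.any(self.percent < 0):
            raise ValidationError("percent values must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)


def read_poll_series(path, dialect: str | None = None,
                     baseline: np.ndarray | None = None) -> PollSeries:
    """Read a poll series CSV.

    Two dialects are supported and auto-detected from the header:

    * ``counts``:       ``date,n1,n2,n3,n4`` — non-negative integer counts.
    * ``proportions``:  ``date,p1,p2,p3,p4`` — rows summing to 1 within
      ±1.5% (percent tables rounded to one decimal pass); rows are
      re-normalized after parsing.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "date" not in cols:
        raise ValidationError(f"{path}: missing 'date' column")
    if dialect is None:
        if {"n1", "n2", "n3", "n4"} <= set(cols):
            dialect = "counts"
        elif {"p1", "p2", "p3", "p4"} <= set(cols):
            dialect = "proportions"
        else:
            raise ValidationError(
                f"{path}: expected columns n1..n4 or p1..p4, got {cols}")
    if df.empty:
        raise ValidationError(f"{path}: empty poll table")
    dates = _as_dates(df["date"])
    if dialect == "counts":
        counts = df[["n1", "n2", "n3", "n4"]].to_numpy()
        if np.any(counts < 0):
            raise ValidationError(f"{path}: negative response count")
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise ValidationError(f"{path}: poll with zero total responses")
        proportions = counts / totals[:, None]
    elif dialect == "proportions":
        counts = None
        proportions = df[["p1", "p2", "p3", "p4"]].to_numpy(dtype=float)
        if np.any(proportions < 0):
            raise ValidationError(f"{path}: negative proportion")
        sums = proportions.sum(axis=1)
        lo, hi = PROPORTION_SUM_RANGE
        bad = (sums < lo) | (sums > hi)
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise ValidationError(
                f"{path}: row {i} proportions sum to {sums[i]:.4f}, "
                f"outside [{lo}, {hi}]")
        proportions = proportions / sums[:, None]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    kwargs = {} if baseline is None else {"baseline": baseline}
    return PollSeries(dates=dates, proportions=proportions, counts=counts,
                      **kwargs)


def read_hospital_registry(path, min_annual: int = 100) -> HospitalRegistry:
    """Read a ``hospital_id,annual_ga_count`` CSV and keep hospitals with at
    least ``min_annual`` annual cases."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty registry file") from None
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"hospital_id", "annual_ga_count"} <= set(df.columns):
        raise ValidationError(
            f"{path}: expected columns hospital_id,annual_ga_count")
    counts = pd.to_numeric(df["annual_ga_count"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValidationError(f"{path}: unparseable count at row {i}")
    keep = counts >= min_annual
    if not keep.any():
        raise ValidationError(
            f"{path}: no hospital with annual count >= {min_annual}")
    return HospitalRegistry(hospital_id=list(df.loc[keep, "hospital_id"]),
                            annual_count=counts[keep].to_numpy())


def read_reference_series(path) -> ReferenceSeries:
    """Read a ``date,percent`` CSV."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"date", "percent"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns date,percent")
    return ReferenceSeries(dates=_as_dates(df["date"]),
                           percent=df["percent"].to_numpy(dtype=float))


def write_estimates(series, path) -> None:
    """Write a volume-estimate series, one row per poll date.

    Columns: ``date,median,ci_low,ci_high,percent_of_baseline``.  Values are
    written in full float precision so a round trip is lossless to 1e-9.
    """
    if len(series.dates) == 0:
        raise ValidationError("cannot write an empty estimate series")
    df = pd.DataFrame({
        "date": [d.isoformat() for d in series.dates],
        "median": series.median,
        "ci_low": series.ci_low,
        "ci_high": series.ci_high,
        "percent_of_baseline": series.percent_of_baseline,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_estimates(path):
    """Round-trip reader for :func:`write_estimates` output."""
    from .volume_simulation import VolumeEstimateSeries

    df = pd.read_csv(path)
    return VolumeEstimateSeries(
        dates=_as_dates(df["date"]),
        median=df["median"].to_numpy(dtype=float),
        ci_low=df["ci_low"].to_numpy(dtype=float),
        ci_high=df["ci_high"].to_numpy(dtype=float),
        percent_of_baseline=df["percent_of_baseline"].to_numpy(dtype=float),
    )


def write_registry(registry: HospitalRegistry, path) -> None:
    pd.DataFrame({"hospital_id": registry.hospital_id,
                  "annual_ga_count": registry.annual_count}).to_csv(
        path, index=False, float_format="%.17g")


def write_poll_series(polls: PollSeries, path) -> None:
    if polls.counts is not None:
        df = pd.DataFrame(polls.counts, columns=["n1", "n2", "n3", "n4"])
    else:
        df = pd.DataFrame(polls.proportions, columns=["p1", "p2", "p3", "p4"])
    df.insert(0, "date", [d.isoformat() for d in polls.dates])
    df.to_csv(path, index=False, float_format="%.17g")


def write_reference_series(ref: ReferenceSeries, path) -> None:
    pd.DataFrame({"date": [d.isoformat() for d in ref.dates],
                  "percent": ref.percent}).to_csv(
        path, index=False, float_format="%.17g")
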