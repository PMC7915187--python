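"""Align an estimate series with an external reference and correlate them.

The two series are observed on different dates, so one is linearly
interpolated (in calendar-day units) to the other's dates before computing
the product-moment correlation coefficient and a t-approximation p-value.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .io_tables import ReferenceSeries
from .volume_simulation import VolumeEstimateSeries


@dataclass
class ComparisonResult:
    r: float
    n: int
    p_value: float
    aligned: list[tuple[dt.date, float, float]]
    n_dropped: int = 0
    p_value_method: str = "t-approximation"

    def to_json(self, path) -> None:
        payload = {
            "r": self.r, "n": self.n, "p_value": self.p_value,
            "n_dropped": self.n_dropped,
            "p_value_method": self.p_value_method,
            "aligned": [
                {"date": d.isoformat(), "estimate": fe, "reference": fr}
                for d, fe, fr in self.aligned],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ordinals(dates) -> np.ndarray:
    return np.array([d.toordinal() for d in dates], dtype=float)


def interpolate_to_dates(dates, values, query_dates) -> np.ndarray:
    """Piecewise-linear interpolation at query dates; no extrapolation."""
    x = _ordinals(dates)
    q = _ordinals(query_dates)
    if np.any(q < x[0]) or np.any(q > x[-1]):
        raise ValueError("query dates outside the observed range "
                         f"[{dates[0]}, {dates[-1]}]")
    return np.interp(q, x, np.asarray(values, dtype=float))


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Centered product-moment correlation."""
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        raise ValueError("zero variance in one of the series")
    return float((da @ db) / denom)


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    if n < 3:
        raise ValueError("need at least 3 aligned points for a p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def compare_series(estimates: VolumeEstimateSeries, reference: ReferenceSeries,
                   direction: str = "estimates_to_reference") -> ComparisonResult:
    """Correlate percent-of-baseline estimates with the reference series.

    By default the estimates are interpolated to the reference dates (the
    reference being the sparser, externally fixed series); pass
    ``direction="reference_to_estimates"`` to invert.  Reference points
    outside the estimate date range are dropped and counted.
    """
    if direction == "estimates_to_reference":
        knot_dates, knot_vals = estimates.dates, estimates.percent_of_baseline
        query_dates, query_vals = list(reference.dates), reference.percent
    elif direction == "reference_to_estimates":
        knot_dates, knot_vals = list(reference.dates), reference.percent
        query_dates, query_vals = estimates.dates, estimates.percent_of_baseline
    else:
        raise ValueError(f"unknown direction {direction!r}")

    lo, hi = knot_dates[0], knot_dates[-1]
    keep = [i for i, d in enumerate(query_dates) if lo <= d <= hi]
    n_dropped = len(query_dates) - len(keep)
    if len(keep) < 3:
        raise ValueError("fewer than 3 overlapping points between the series")
    q_dates = [query_dates[i] for i in keep]
    q_vals = np.asarray(query_vals, dtype=float)[keep]
    interp = interpolate_to_dates(knot_dates, knot_vals, q_dates)

    if direction == "estimates_to_reference":
        est_vals, ref_vals = interp, q_vals
    else:
        est_vals, ref_vals = q_vals, interp
    r = pearson_r(est_vals, ref_vals)
    n = len(keep)
    return ComparisonResult(
        r=r, n=n, p_value=correlation_p_value(r, n),
        aligned=[(d, float(e), float(f))
                 for d, e, f in zip(q_dates, est_vals, ref_vals)],
        n_dropped=n_dropped)
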