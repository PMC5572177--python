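"""Kaplan–Meier survival and discounted restricted mean survival time.

The health effect in the within-trial analysis is life expectancy restricted
to the trial horizon, computed as the area under the Kaplan–Meier curve for
time to ovarian-cancer death.  Discounting follows an annual-step
convention: survival experienced during follow-up year ``k`` (0-indexed) is
weighted by ``(1 + d)^{-k}``, so the first year is undiscounted.  With
near-certain survival over ~13.56 years this convention yields restricted
means of ~12.37 (1.5%) and ~11.02 (3.5%), the magnitudes reported in
large screening trials of this kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "KMCurve",
    "RMSTResult",
    "EffectDifference",
    "km_estimate",
    "restricted_mean",
    "effect_difference",
    "table2_frame",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with risk-set bookkeeping.

    ``times`` are the distinct observed times (events and censorings);
    ``survival`` is the step function value at (just after) each time;
    ``at_risk``/``n_events`` give the risk set and death count at each time;
    ``variance`` is the Greenwood variance of the survival estimate.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray
    max_time: float

    def survival_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t) as a right-continuous step function, S(0)=1."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RMSTResult:
    horizon: float
    discount_rate: float
    estimate: float
    std_error: float

    @property
    def variance(self) -> float:
        return self.std_error ** 2


@dataclass(frozen=True)
class EffectDifference:
    estimate: float
    variance: float
    horizon: float
    discount_rate: float

    @property
    def std_error(self) -> float:
        return math.sqrt(self.variance)


def km_estimate(records: pd.DataFrame, arm: str | None = None) -> KMCurve:
    """Kaplan–Meier estimate of time to ovarian-cancer death.

    ``event == 1`` is a death, ``event == 0`` right-censoring; deaths are
    processed before censorings at tied times (the product-limit
    convention).
    """
    if arm is not None:
        records = records[records["arm"] == arm]
    if len(records) == 0:
        raise ValueError(f"no records in arm {arm!r}")
    t = records["followup_time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    n_events = table["observed"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, 1.0 - n_events / at_risk, 1.0)
    survival = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    denom = at_risk * (at_risk - n_events)
    terms = np.where(denom > 0, n_events / np.where(denom > 0, denom, 1.0), 0.0)
    variance = survival ** 2 * np.cumsum(terms)
    return KMCurve(times=times, survival=survival, at_risk=at_risk,
                   n_events=n_events, variance=variance, max_time=float(t.max()))


def _discount_weight(t: np.ndarray, rate: float) -> np.ndarray:
    return (1.0 + rate) ** (-np.floor(t + 1e-12))


def _tail_areas(curve: KMCurve, horizon: float, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoint grid on [0, horizon] and the remaining weighted area.

    Returns ``(grid, tail)`` where ``tail[i]`` is the integral of
    ``(1+rate)^(-floor(t)) * S(t)`` over ``[grid[i], horizon]``; the grid
    contains 0, every curve step time below the horizon, every integer
    year, and the horizon itself, so areas from any of those points are a
    single lookup.
    """
    cuts = np.concatenate([
        [0.0, horizon],
        np.arange(1.0, math.ceil(horizon)),
        curve.times[(curve.times > 0) & (curve.times < horizon)],
    ])
    grid = np.unique(cuts)
    lefts = grid[:-1]
    widths = np.diff(grid)
    s = np.atleast_1d(curve.survival_at(lefts))
    w = _discount_weight(lefts, rate)
    seg = w * s * widths
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return grid, tail


def _weighted_area(curve: KMCurve, start: float, stop: float, rate: float) -> float:
    """Integral of (1+rate)^(-floor(t)) * S(t) dt over [start, stop]."""
    if stop <= start:
        return 0.0
    grid, tail = _tail_areas(curve, stop, rate)
    idx = np.searchsorted(grid, start)
    if idx < len(grid) and math.isclose(grid[idx], start):
        return float(tail[idx])
    # start between breakpoints: subtract the partial leading segment
    prev = idx - 1
    partial = float(tail[prev]) if prev >= 0 else float(tail[0])
    if prev >= 0:
        w = float(_discount_weight(np.array([grid[prev]]), rate)[0])
        s = float(curve.survival_at(grid[prev]))
        partial -= w * s * (start - grid[prev])
    return partial


def restricted_mean(curve: KMCurve, horizon: float,
                    discount_rate: float = 0.0) -> RMSTResult:
    """Discounted restricted mean survival from a Kaplan–Meier curve.

    The point estimate is the discount-weighted area under the survival
    step function up to ``horizon``.  The standard error generalises the
    usual restricted-mean Greenwood-type variance: for each event time
    ``t_i <= horizon`` the remaining weighted area ``A(t_i)`` enters as

        Var = sum_i A(t_i)^2 * d_i / (n_i (n_i - d_i)).

    Horizons beyond the largest observed time are refused — the estimator
    never extrapolates silently.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    if horizon > curve.max_time + 1e-9:
        raise ValueError(
            f"horizon {horizon} exceeds the largest observed time {curve.max_time}; "
            "use the extrapolation module for beyond-trial projection"
        )
    grid, tail = _tail_areas(curve, horizon, discount_rate)
    estimate = float(tail[0])

    mask = (curve.n_events > 0) & (curve.times < horizon) & \
           (curve.at_risk - curve.n_events > 0)
    idx = np.searchsorted(grid, curve.times[mask])
    areas = tail[idx]
    n_i, d_i = curve.at_risk[mask], curve.n_events[mask]
    var = float(np.sum(areas ** 2 * d_i / (n_i * (n_i - d_i))))
    return RMSTResult(horizon=horizon, discount_rate=discount_rate,
                      estimate=estimate, std_error=math.sqrt(var))


def effect_difference(a: RMSTResult, b: RMSTResult) -> EffectDifference:
    """Difference in (discounted) restricted mean survival, a - b.

    Arms are independent, so the variance is the sum of the arm variances.
    """
    if not math.isclose(a.horizon, b.horizon):
        raise ValueError("horizons differ")
    if not math.isclose(a.discount_rate, b.discount_rate):
        raise ValueError("discount rates differ")
    return EffectDifference(estimate=a.estimate - b.estimate,
                            variance=a.variance + b.variance,
                            horizon=a.horizon, discount_rate=a.discount_rate)


def common_horizon(records: pd.DataFrame) -> float:
    """Largest restriction time at which every arm's curve is defined:
    the minimum over arms of the arm's largest observed time."""
    return float(records.groupby("arm")["followup_time"].max().min())


def table2_frame(records: pd.DataFrame, discount_rates: tuple[float, ...] = (0.0, 0.015, 0.035),
                 horizon: float | None = None) -> pd.DataFrame:
    """Per-arm restricted mean time to ovarian-cancer death, by discount rate.

    ``horizon`` defaults to :func:`common_horizon` of the data.
    """
    if horizon is None:
        horizon = common_horizon(records)
    rows = []
    for arm in sorted(records["arm"].unique()):
        curve = km_estimate(records, arm)
        for rate in discount_rates:
            res = restricted_mean(curve, horizon, rate)
            rows.append({"arm": arm, "discount_rate": rate,
                         "mean": res.estimate, "se": res.std_error})
    return pd.DataFrame(rows)
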