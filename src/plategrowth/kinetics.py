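"""Exponential-phase growth-rate and doubling-time estimation.

The growth rate mu (1/h) of a culture is the slope of the best-fit line
through ln(OD) versus time over the exponential phase, and the doubling
time is t_d = ln2 / mu (hours per cycle).  The exponential window is found
by enumerating every contiguous run of at least ``min_points`` scheduled
times inside the search interval (default 12-20 h, endpoints inclusive) and
choosing, among runs whose linear fit reaches the R^2 threshold (default
0.98), the longest — ties broken by higher R^2, then earlier start.  If no
run reaches the threshold the best-R^2 run is used and the fit is flagged
rather than rejected, so a whole-plate analysis never aborts on one noisy
well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .plate_model import GrowthCurve, log_transform

__all__ = [
    "WindowConfig",
    "FitWindow",
    "GrowthFit",
    "DoublingTimeComparison",
    "ols_fit",
    "select_exponential_window",
    "estimate_growth_fit",
    "percent_diff",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class WindowConfig:
    """Search settings for the exponential window."""

    interval_start_h: float = 12.0
    interval_end_h: float = 20.0
    min_points: int = 3
    r2_threshold: float = 0.98

    def __post_init__(self) -> None:
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3 for a meaningful R^2")
        if self.interval_end_h <= self.interval_start_h:
            raise ValueError("interval end must exceed start")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")


@dataclass(frozen=True)
class FitWindow:
    """A contiguous run of scheduled times used for the exponential fit."""

    times: tuple[float, ...]
    indices: tuple[int, ...]

    @property
    def start(self) -> float:
        return self.times[0]

    @property
    def end(self) -> float:
        return self.times[-1]

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """Result of an exponential-window fit on one curve."""

    window: FitWindow
    slope: float  # growth rate mu, 1/h
    intercept: float  # ln-OD units
    r2: float
    td: float  # doubling time, h per cycle
    below_threshold_flag: bool

    @property
    def mu(self) -> float:
        return self.slope


@dataclass(frozen=True)
class DoublingTimeComparison:
    """Percent difference in doubling time relative to a reference condition.

    Positive means slower growth under the treatment.
    """

    td_treatment: float
    td_reference: float
    pct_diff: float

    @classmethod
    def of(cls, td_treatment: float, td_reference: float) -> "DoublingTimeComparison":
        return cls(td_treatment, td_reference, percent_diff(td_treatment, td_reference))


def ols_fit(times, y) -> tuple[float, float, float]:
    """Closed-form simple OLS of *y* on *times*: (slope, intercept, r2).

    R^2 = 1 - SS_res/SS_tot.  When *y* has zero variance, R^2 is 1 if the
    residuals are exactly zero (a flat line fits perfectly) and 0 otherwise.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("times and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for a fit, got {len(x)}")
    xm = x.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate times: all equal")
    ym = y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def _candidate_runs(indices: list[int], min_points: int) -> list[tuple[int, ...]]:
    runs = []
    n = len(indices)
    for length in range(min_points, n + 1):
        for start in range(0, n - length + 1):
            runs.append(tuple(indices[start : start + length]))
    return runs


def select_exponential_window(
    curve: GrowthCurve, config: WindowConfig = WindowConfig()
) -> tuple[FitWindow, bool]:
    """Choose the strongest-linearity window of a curve's ln(OD) trace.

    Returns ``(window, below_threshold_flag)``; the flag is set when no
    candidate run reaches the R^2 threshold.  Raises if fewer than
    ``min_points`` scheduled times fall inside the search interval.
    """
    ln_curve = curve if curve.log_space else log_transform(curve)
    idx = ln_curve.schedule.indices_in(config.interval_start_h, config.interval_end_h)
    if len(idx) < config.min_points:
        raise ValueError(
            f"only {len(idx)} scheduled time(s) in "
            f"[{config.interval_start_h}, {config.interval_end_h}] h; "
            f"need >= {config.min_points}"
        )
    times = ln_curve.schedule.as_array()
    y = ln_curve.od

    scored = []
    for run in _candidate_runs(idx, config.min_points):
        _, _, r2 = ols_fit(times[list(run)], y[list(run)])
        scored.append((run, r2))

    passing = [(run, r2) for run, r2 in scored if r2 >= config.r2_threshold]
    if passing:
        # longest run; ties -> higher R^2, then earlier start
        run, _ = max(passing, key=lambda s: (len(s[0]), s[1], -s[0][0]))
        flag = False
    else:
        run, _ = max(scored, key=lambda s: (s[1], len(s[0]), -s[0][0]))
        flag = True
    window = FitWindow(times=tuple(float(times[i]) for i in run), indices=run)
    return window, flag


def estimate_growth_fit(
    curve: GrowthCurve, config: WindowConfig = WindowConfig()
) -> GrowthFit:
    """ln-transform, select the exponential window, fit, and derive t_d.

    Raises on non-positive OD and on a non-positive fitted slope (doubling
    time undefined).
    """
    ln_curve = curve if curve.log_space else log_transform(curve)
    window, flag = select_exponential_window(ln_curve, config)
    idx = list(window.indices)
    slope, intercept, r2 = ols_fit(
        ln_curve.schedule.as_array()[idx], ln_curve.od[idx]
    )
    if slope <= 0:
        raise ValueError(
            f"non-positive growth rate ({slope:.4g}/h) for {curve.key}: "
            "doubling time undefined"
        )
    return GrowthFit(
        window=window,
        slope=slope,
        intercept=intercept,
        r2=r2,
        td=LN2 / slope,
        below_threshold_flag=flag,
    )


def percent_diff(td_treatment: float, td_reference: float) -> float:
    """Percent change in doubling time relative to the reference.

    100 * (td_treatment - td_reference) / td_reference; positive means the
    treatment slowed growth.
    """
    if not td_reference > 0:
        raise ValueError(f"reference doubling time must be > 0, got {td_reference}")
    return 100.0 * (td_treatment - td_reference) / td_reference
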