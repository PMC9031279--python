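"""Sterile-male field survival from daily cohort recaptures.

A cohort of marked sterile males is released once and its members are
recaptured on daily-serviced traps. Assuming a constant probability of daily
survival (PDS), the expected recapture count declines geometrically, so the
slope of log10(recaptures) against trapping day estimates log10(PDS).

Because recaptured flies are removed from the population, raw counts decline
faster than mortality alone would dictate. When the recaptured fraction is
non-trivial (here ~10%), each day's count is first scaled up by
``R / (R - captures before that day)`` — the removal adjustment: it adds back
the flies that would have been caught had earlier captures not removed them.
The adjusted series is smoothed with a centred three-day moving average
before the log-linear fit.

Derived longevity metrics under geometric survival:

* ``PDS = 10**slope``
* half-life ``HL = ln(0.5) / ln(PDS)`` (days)
* average life expectancy ``ALE = -1 / ln(PDS)`` (days)

Replicate cohorts whose regression slope is not significantly negative are
excluded from the aggregate, mirroring standard practice for MRR longevity
studies.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .field_data import ReleaseEvent, TrapObservation, day_index

__all__ = [
    "CohortSeries",
    "SurvivalEstimate",
    "ReplicateAggregate",
    "adjust_recaptures",
    "moving_average_3",
    "fit_log_decline",
    "derive_metrics",
    "aggregate_replicates",
    "estimate_cohort_survival",
    "cohort_series_from_logs",
]


@dataclass(frozen=True)
class CohortSeries:
    """Daily recaptures of one colour-marked release cohort.

    ``raw_counts[t]`` is the number recaptured on day ``day_index[t]`` (day 1
    = release day + 1, the first day traps could catch a released fly).
    ``adjusted_counts`` is filled by :func:`adjust_recaptures`.
    """

    colour: str
    release_size: int
    day_index: tuple[int, ...]
    raw_counts: tuple[int, ...]
    adjusted_counts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.release_size <= 0:
            raise ValueError(f"release_size must be positive (got {self.release_size})")
        if len(self.day_index) != len(self.raw_counts):
            raise ValueError("day_index and raw_counts length mismatch")
        if any(c < 0 for c in self.raw_counts):
            raise ValueError("negative recapture count")
        if sum(self.raw_counts) > self.release_size:
            raise ValueError("cumulative recaptures exceed release size")


@dataclass(frozen=True)
class SurvivalEstimate:
    """Log-linear decline fit and its derived longevity metrics."""

    slope: float                # per day, log10 scale
    pds: float                  # probability of daily survival, 10**slope
    half_life_days: float       # nan when slope >= 0
    ale_days: float             # nan when slope >= 0
    fit_p_value: float
    r_squared: float
    significant: bool
    n_days_fit: int
    colour: str = ""


@dataclass(frozen=True)
class ReplicateAggregate:
    """Mean and sample SD of survival metrics over significant replicates."""

    n_total: int
    n_significant: int
    slope_mean: float
    slope_sd: float
    pds_mean: float
    pds_sd: float
    half_life_mean: float
    half_life_sd: float
    ale_mean: float
    ale_sd: float


def adjust_recaptures(cohort: CohortSeries) -> CohortSeries:
    """Scale daily counts to compensate for trap removal of marked flies.

    ``adjusted[t] = raw[t] * R / (R - sum(raw[:t]))`` — the denominator is
    the number still uncaptured at the start of day *t*, so the day-1 factor
    is exactly 1 and the series is unchanged when all counts are zero.
    """
    R = cohort.release_size
    adjusted: list[float] = []
    captured_before = 0
    for raw in cohort.raw_counts:
        remaining = R - captured_before
        if remaining <= 0 and raw > 0:
            raise ValueError(
                "cumulative captures reached the release size before the series ended"
            )
        adjusted.append(raw * R / remaining if raw > 0 else float(raw))
        captured_before += raw
    return replace(cohort, adjusted_counts=tuple(adjusted))


def moving_average_3(series: Sequence[float]) -> np.ndarray:
    """Centred three-point moving average; output is 2 shorter than input.

    Output element *i* is the mean over input days ``i, i+1, i+2`` — i.e. the
    smoothed value indexed to the centre day. Endpoints are truncated, not
    padded, so no artificial values leak into the regression.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 3:
        raise ValueError(f"need at least 3 points for a 3-day moving average (got {arr.size})")
    return np.convolve(arr, np.ones(3) / 3.0, mode="valid")


def derive_metrics(slope: float) -> tuple[float, float, float]:
    """PDS, half-life and average life expectancy from a log10-scale slope.

    Only defined for a declining series (slope < 0): a flat or rising fit has
    no finite half-life.
    """
    if not slope < 0:
        raise ValueError(f"longevity metrics require a negative slope (got {slope})")
    pds = 10.0 ** slope
    half_life = math.log(0.5) / math.log(pds)
    ale = -1.0 / math.log(pds)
    return pds, half_life, ale


def fit_log_decline(
    smoothed: Sequence[float],
    day_index: Sequence[int] | None = None,
    alpha: float = 0.05,
    colour: str = "",
) -> SurvivalEstimate:
    """OLS of log10(smoothed recaptures) on trapping day.

    Days with a zero smoothed value are dropped (no pseudo-count is added);
    at least three positive values must remain. The slope is tested two-sided
    against zero; the fit is flagged ``significant`` when p < alpha **and**
    the slope is negative. Metrics are still returned for a non-significant
    fit so that replicate screening stays auditable.
    """
    y = np.asarray(smoothed, dtype=float)
    x = np.arange(1, y.size + 1, dtype=float) if day_index is None else np.asarray(day_index, dtype=float)
    if x.size != y.size:
        raise ValueError("day_index and smoothed series length mismatch")
    if np.all(y == 0):
        raise ValueError("no signal: all smoothed recapture values are zero")
    keep = y > 0
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 positive smoothed values to fit (got {x.size})")

    fit = stats.linregress(x, np.log10(y))
    slope = float(fit.slope)
    p_value = float(fit.pvalue)
    r_squared = float(fit.rvalue**2)
    significant = bool(p_value < alpha and slope < 0)
    if slope < 0:
        pds, hl, ale = derive_metrics(slope)
    else:
        pds, hl, ale = 10.0 ** slope, float("nan"), float("nan")
    return SurvivalEstimate(
        slope=slope,
        pds=pds,
        half_life_days=hl,
        ale_days=ale,
        fit_p_value=p_value,
        r_squared=r_squared,
        significant=significant,
        n_days_fit=int(x.size),
        colour=colour,
    )


def aggregate_replicates(estimates: Sequence[SurvivalEstimate]) -> ReplicateAggregate:
    """Mean ± sample SD of slope/PDS/HL/ALE over the significant replicates.

    Replicates whose regression did not reach significance are excluded from
    the aggregate (their count is still reported). A single significant
    replicate yields SD = nan (not applicable).
    """
    significant = [e for e in estimates if e.significant]
    if not significant:
        raise ValueError("no replicate has a significant declining fit")

    def _ms(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        return float(arr.mean()), sd

    slope_m, slope_s = _ms([e.slope for e in significant])
    pds_m, pds_s = _ms([e.pds for e in significant])
    hl_m, hl_s = _ms([e.half_life_days for e in significant])
    ale_m, ale_s = _ms([e.ale_days for e in significant])
    return ReplicateAggregate(
        n_total=len(estimates),
        n_significant=len(significant),
        slope_mean=slope_m,
        slope_sd=slope_s,
        pds_mean=pds_m,
        pds_sd=pds_s,
        half_life_mean=hl_m,
        half_life_sd=hl_s,
        ale_mean=ale_m,
        ale_sd=ale_s,
    )


def estimate_cohort_survival(cohort: CohortSeries, alpha: float = 0.05) -> SurvivalEstimate:
    """Full pipeline for one cohort: removal adjustment -> 3-day MA -> fit."""
    adjusted = adjust_recaptures(cohort)
    smoothed = moving_average_3(adjusted.adjusted_counts)
    # MA output is centred: its first element sits on the cohort's 2nd day
    centre_days = list(cohort.day_index[1:-1])
    return fit_log_decline(smoothed, centre_days, alpha=alpha, colour=cohort.colour)


def cohort_series_from_logs(
    traps: Iterable[TrapObservation],
    releases: Iterable[ReleaseEvent],
    colour: str,
    n_days: int = 14,
) -> CohortSeries:
    """Build a cohort's daily recapture series from trap and release logs.

    Recaptures are pooled over all included traps per collection day. The
    cohort's release day is the earliest release of that colour; day 1 of
    the series is the release day itself (flies are at risk of capture from
    the moment of release) and the series spans the ``n_days`` trapping
    horizon.
    """
    cohort_releases = [r for r in releases if r.colour == colour and r.count > 0]
    if not cohort_releases:
        raise ValueError(f"no releases found for colour {colour!r}")
    release_day: _dt.date = min(r.date for r in cohort_releases)
    release_size = sum(r.count for r in cohort_releases if r.date == release_day)

    counts = [0] * n_days
    for obs in traps:
        if not obs.included_in_analysis:
            continue
        d = day_index(obs.date_collected, release_day)  # release day -> 1
        if 1 <= d <= n_days:
            counts[d - 1] += obs.sterile_counts.get(colour, 0)
    return CohortSeries(
        colour=colour,
        release_size=release_size,
        day_index=tuple(range(1, n_days + 1)),
        raw_counts=tuple(counts),
    )
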