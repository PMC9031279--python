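"""Weekly per-trap female means and suppression relative to control sites.

The standardised unit of wild-population pressure is the total number of
wild females per sticky trap per week: collections within a week are summed
per trap (biweekly collections become weekly totals), then averaged across
the site's included traps. Because weekly counts are volatile, suppression
is read off three-week moving averages:

    suppression% = 100 * (1 - treated_MA / control_MA)

computed against each control site separately — control sites can differ
substantially from one another, and pooling would hide that. Negative
suppression (treated worse than control) is reported, not clipped.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .field_data import TrapObservation, assign_week

__all__ = [
    "weekly_female_means",
    "three_week_ma",
    "suppression",
    "recapture_rate",
    "suppression_table",
]


def weekly_female_means(traps: Iterable[TrapObservation], site: str) -> pd.DataFrame:
    """Mean (±SE) wild females per trap per week at one site.

    Each trap's female counts are summed over its collections within an ISO
    week; the mean and standard error are taken across the site's included
    traps. Traps with no collection in a week contribute a zero total for
    that week (a serviced trap that caught nothing and an unserviced trap
    are not distinguishable from counts alone).
    """
    per_trap: dict[int, dict[str, int]] = {}
    trap_ids: set[str] = set()
    for obs in traps:
        if obs.site_id != site or not obs.included_in_analysis:
            continue
        trap_ids.add(obs.trap_id)
        wk = per_trap.setdefault(assign_week(obs.date_collected), {})
        wk[obs.trap_id] = wk.get(obs.trap_id, 0) + obs.wild_female_count
    if not trap_ids:
        raise ValueError(f"no included trap observations for site {site!r}")

    n = len(trap_ids)
    records = []
    for week in sorted(per_trap):
        totals = np.array([per_trap[week].get(t, 0) for t in sorted(trap_ids)], dtype=float)
        se = float(np.std(totals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        records.append(
            {
                "site_id": site,
                "week": week,
                "mean_females_per_trap": float(totals.mean()),
                "se": se,
                "n_traps": n,
            }
        )
    return pd.DataFrame.from_records(records)


def three_week_ma(series: pd.Series, align: str = "centred") -> pd.Series:
    """Three-week moving average of a week-indexed series.

    Weeks must be contiguous integers. ``align="centred"`` (default) indexes
    each window mean to its middle week with endpoint truncation;
    ``align="trailing"`` indexes it to the last week of the window.
    """
    if align not in ("centred", "trailing"):
        raise ValueError(f"align must be 'centred' or 'trailing' (got {align!r})")
    weeks = np.asarray(series.index, dtype=int)
    if weeks.size < 3:
        raise ValueError(f"need >= 3 weeks for a 3-week moving average (got {weeks.size})")
    if not np.all(np.diff(weeks) == 1):
        raise ValueError("week sequence must be contiguous")
    values = np.convolve(series.to_numpy(dtype=float), np.ones(3) / 3.0, mode="valid")
    idx = weeks[1:-1] if align == "centred" else weeks[2:]
    return pd.Series(values, index=pd.Index(idx, name="week"))


def suppression(treated_ma: float, control_ma: float) -> float:
    """Percent suppression of the treated site relative to one control site.

    ``100 * (1 - treated/control)``; undefined (nan) when the control mean
    is zero. May be negative when the treated site outpaces the control.
    """
    if control_ma < 0 or treated_ma < 0:
        raise ValueError("moving averages must be non-negative")
    if control_ma == 0:
        return float("nan")
    return 100.0 * (1.0 - treated_ma / control_ma)


def recapture_rate(total_recaptured: int, total_released: int) -> float:
    """Percent of released marked males recaptured, to two decimals."""
    if total_released < 1:
        raise ValueError("total_released must be >= 1")
    if total_recaptured < 0:
        raise ValueError("total_recaptured must be non-negative")
    if total_recaptured > total_released:
        raise ValueError(
            f"recaptured ({total_recaptured}) exceeds released ({total_released})"
        )
    return round(100.0 * total_recaptured / total_released, 2)


def suppression_table(
    traps: Iterable[TrapObservation],
    treated: str,
    controls: Sequence[str],
    align: str = "centred",
) -> pd.DataFrame:
    """Weekly suppression of the treated site against each control site.

    Columns: per-site weekly means/SE, three-week MAs, and one suppression
    column per control. Restricted to weeks where all sites report.
    """
    traps = list(traps)
    sites = [treated, *controls]
    means = {s: weekly_female_means(traps, s).set_index("week") for s in sites}
    common = sorted(set.intersection(*(set(m.index) for m in means.values())))
    if len(common) < 3:
        raise ValueError("need >= 3 common weeks across sites")
    weeks = pd.Index(common, name="week")

    out = pd.DataFrame(index=weeks)
    mas = {}
    for s in sites:
        out[f"mean_{s}"] = means[s].loc[weeks, "mean_females_per_trap"]
        out[f"se_{s}"] = means[s].loc[weeks, "se"]
        mas[s] = three_week_ma(out[f"mean_{s}"], align=align)
        out[f"ma_{s}"] = mas[s]
    for c in controls:
        out[f"suppression_vs_{c}"] = [
            suppression(mas[treated][w], mas[c][w]) if w in mas[treated].index else math.nan
            for w in weeks
        ]
    return out
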