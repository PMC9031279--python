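"""Standing crop of sterile males and weekly wild-male abundance.

The daily *standing crop* — the expected number of released sterile males
still alive — follows the recursion

    SS[d] = SS[d-1] * PDS + R[d]

where ``R[d]`` is the number released on day *d* and PDS the probability of
daily survival. Trap removals are ignored: over a season they amount to a
couple of percent of releases and the recursion carries no removal term.

The weekly wild-male standing crop is inferred from the trap ratio: if S
sterile and W wild males were trapped in a week, and both are sampled with
the same capture probability, then

    SW = (W / S) * mean weekly sterile standing crop

Weeks in which no sterile males were trapped (S = 0) leave SW undefined and
are reported as missing, as are sterile:wild ratios in weeks with W = 0.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .field_data import ReleaseEvent, TrapObservation, assign_week

__all__ = [
    "standing_crop",
    "weekly_mean",
    "wild_standing_crop",
    "sterile_to_wild_ratio",
    "abundance_table",
]


def standing_crop(
    releases: Mapping | pd.Series,
    pds: float,
    initial: float = 0.0,
) -> pd.Series:
    """Daily sterile-male standing crop from a day->release-count mapping.

    ``releases`` maps dates (or integer day indices) to males released that
    day; days between the first and last key with no entry count as zero
    releases. Returns a Series over the full contiguous day range.
    """
    if not (0 < pds <= 1):
        raise ValueError(f"pds must be in (0, 1] (got {pds})")
    rel = pd.Series(releases, dtype=float).sort_index()
    if rel.empty:
        return pd.Series(dtype=float)
    if (rel < 0).any():
        raise ValueError("release counts must be non-negative")

    idx = rel.index
    if isinstance(idx[0], (int, np.integer)):
        full = pd.RangeIndex(int(idx[0]), int(idx[-1]) + 1)
        rel = rel.reindex(full, fill_value=0.0)
    else:
        full = pd.date_range(pd.Timestamp(idx[0]), pd.Timestamp(idx[-1]), freq="D")
        rel.index = pd.to_datetime(rel.index)
        rel = rel.groupby(level=0).sum().reindex(full, fill_value=0.0)

    ss = np.empty(len(rel))
    prev = initial
    for i, r in enumerate(rel.to_numpy()):
        prev = prev * pds + r
        ss[i] = prev
    return pd.Series(ss, index=rel.index, name="sterile_standing_crop")


def weekly_mean(series: pd.Series) -> pd.Series:
    """Arithmetic mean of daily values within each ISO week.

    Weeks are identified by ISO week number; the mean is over whichever days
    of the week are present in the series (all 7 for interior weeks).
    """
    if series.empty:
        return pd.Series(dtype=float)
    idx = pd.to_datetime(series.index)
    weeks = idx.isocalendar().week.to_numpy()
    out = pd.Series(series.to_numpy(), index=weeks).groupby(level=0).mean()
    out.index.name = "week"
    return out


def wild_standing_crop(wild_caught: int, sterile_caught: int, weekly_mean_sterile: float) -> float:
    """Weekly wild-male standing crop SW = (W / S) x mean sterile standing crop.

    Returns nan when no sterile males were caught that week (S = 0), since
    the ratio-based estimate is then undefined.
    """
    if sterile_caught < 0 or wild_caught < 0:
        raise ValueError("counts must be non-negative")
    if sterile_caught == 0:
        return float("nan")
    return (wild_caught / sterile_caught) * weekly_mean_sterile


def sterile_to_wild_ratio(sterile_caught: int, wild_caught: int) -> float:
    """Overflooding ratio S:W from weekly trap totals; nan when W = 0."""
    if sterile_caught < 0 or wild_caught < 0:
        raise ValueError("counts must be non-negative")
    if wild_caught == 0:
        return float("nan")
    return sterile_caught / wild_caught


def abundance_table(
    releases: Iterable[ReleaseEvent],
    traps: Iterable[TrapObservation],
    pds: float,
    scope: str = "crop",
    site: str | None = None,
) -> pd.DataFrame:
    """Weekly abundance summary: SS̄, trap totals W and S, S:W ratio and SW.

    ``scope`` selects which releases feed the standing crop: ``"crop"``
    (default — wild abundance is estimated under the polytunnels, where only
    crop releases are at risk of capture) or ``"all"``. Trap totals are sums
    over included traps, optionally restricted to one site.
    """
    if scope not in ("crop", "all"):
        raise ValueError(f"scope must be 'crop' or 'all' (got {scope!r})")
    rel_counts: dict = {}
    for ev in releases:
        if scope == "crop" and ev.location_class != "crop":
            continue
        rel_counts[ev.date] = rel_counts.get(ev.date, 0) + ev.count
    if not rel_counts:
        raise ValueError("no releases in scope")
    ss = standing_crop(rel_counts, pds)
    ss_weekly = weekly_mean(ss)

    rows: dict[int, dict[str, int]] = {}
    for obs in traps:
        if not obs.included_in_analysis:
            continue
        if site is not None and obs.site_id != site:
            continue
        wk = assign_week(obs.date_collected)
        agg = rows.setdefault(wk, {"W": 0, "S": 0})
        agg["W"] += obs.wild_male_count
        agg["S"] += obs.sterile_total

    records = []
    for wk in sorted(set(ss_weekly.index) | set(rows)):
        W = rows.get(wk, {}).get("W", 0)
        S = rows.get(wk, {}).get("S", 0)
        ssbar = float(ss_weekly.get(wk, math.nan))
        records.append(
            {
                "week": wk,
                "sterile_standing_crop_mean": ssbar,
                "wild_males_trapped": W,
                "sterile_males_trapped": S,
                "sterile_to_wild_ratio": sterile_to_wild_ratio(S, W),
                "wild_standing_crop": wild_standing_crop(W, S, ssbar) if not math.isnan(ssbar) else math.nan,
            }
        )
    return pd.DataFrame.from_records(records).set_index("week")
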