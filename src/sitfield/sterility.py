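"""Fecundity, fertility and induced-sterility summaries from assay records.

Definitions:

* **fecundity** — eggs laid per female per 24 h. Females that laid nothing
  still count in the denominator.
* **fertility** — percentage of laid eggs that develop to pupae, pooled over
  records; vials in which no eggs were laid are excluded (a female that laid
  nothing tells us nothing about egg viability).
* **induced sterility** — proportional reduction in fertility of a treated
  group relative to its control: ``100 * (1 - treated/control)``.

Laying windows longer than a day (recovery extensions up to 15 days) are
normalised through ``laying_hours`` so fecundity stays per-24 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .field_data import AssayRecord

__all__ = [
    "AssaySummary",
    "fecundity",
    "fertility",
    "per_record_fertility",
    "induced_sterility",
    "summarize_group",
]


@dataclass(frozen=True)
class AssaySummary:
    group: str
    fecundity_eggs_per_female_per_24h: float
    fertility_pct: float                       # pooled: 100 * sum(pupae)/sum(eggs)
    fertility_pct_mean: float                  # mean of per-record fertilities
    fertility_pct_sd: float
    n_records: int
    n_females_total: int
    n_females_laying: int


def fecundity(records: Sequence[AssayRecord]) -> float:
    """Eggs per female per 24 h, over all records (zero-egg females included)."""
    records = list(records)
    if not records:
        raise ValueError("no assay records")
    female_days = sum(r.n_females * r.laying_hours / 24.0 for r in records)
    return sum(r.eggs for r in records) / female_days


def fertility(records: Sequence[AssayRecord]) -> float:
    """Pooled egg-to-pupa percentage over records with at least one egg."""
    laying = [r for r in records if r.eggs > 0]
    if not laying:
        raise ValueError("no records with eggs; fertility undefined")
    return 100.0 * sum(r.pupae for r in laying) / sum(r.eggs for r in laying)


def per_record_fertility(records: Iterable[AssayRecord]) -> list[float]:
    """Per-record egg-to-pupa percentages, zero-egg records excluded."""
    return [100.0 * r.pupae / r.eggs for r in records if r.eggs > 0]


def induced_sterility(control_fertility_pct: float, treated_fertility_pct: float) -> float:
    """Percent reduction of treated-group fertility relative to control."""
    if control_fertility_pct <= 0:
        raise ValueError("control fertility must be positive")
    return 100.0 * (1.0 - treated_fertility_pct / control_fertility_pct)


def summarize_group(records: Sequence[AssayRecord], group: str) -> AssaySummary:
    """Full summary for one assay group (both pooled and per-record views)."""
    recs = [r for r in records if r.group == group]
    if not recs:
        raise ValueError(f"no records for group {group!r}")
    per_rec = per_record_fertility(recs)
    sd = float(np.std(per_rec, ddof=1)) if len(per_rec) > 1 else float("nan")
    return AssaySummary(
        group=group,
        fecundity_eggs_per_female_per_24h=fecundity(recs),
        fertility_pct=fertility(recs) if per_rec else math.nan,
        fertility_pct_mean=float(np.mean(per_rec)) if per_rec else math.nan,
        fertility_pct_sd=sd,
        n_records=len(recs),
        n_females_total=sum(r.n_females for r in recs),
        n_females_laying=sum(r.n_females for r in recs if r.eggs > 0),
    )
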