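"""Stochastic simulator of an SIT field-suppression trial.

Generates release logs and trap logs with known ground truth so every
downstream stage (survival estimation, standing crop, suppression) can be
tested against the parameters that generated the data.

Generative model
----------------
* **Sterile males.** Each released fly survives each day with probability
  ``pds_true`` (geometric lifetime). Each fly that is alive and not yet
  captured is caught on a given day with probability ``capture_prob``;
  capture removes it. Survival is applied before capture within a day.
* **Wild population.** Zero until ``wild_seed_week``, then deterministic
  exponential growth by ``wild_growth_rate`` per week (expectation model);
  daily trap captures of wild males and females are Poisson with mean
  ``population x capture_prob``. Trapping does not deplete the wild
  population. There is no published generative model for the wild
  population, so this exponential emulator is a stand-in whose rate is a
  free parameter.
* **Traps.** Daily captures are spread uniformly (multinomially) over the
  site's traps; a configurable number of traps are flagged as excluded from
  analysis, emulating traps disqualified by the trial design.

The default configuration emulates the trial's conditions: biweekly releases
(Tuesday/Friday) ramping from ~9,000 to ~60,000 males per week over ISO
weeks 15-41 of 2021, ~70% under the crop and 30% on the perimeter, released
in vials of 100; sterile-male daily survival 0.80; a per-fly per-day capture
probability of 0.02 (a few percent of released flies recaptured over their
lifetime); wild population seeded in week 27. Two untreated control sites
are generated alongside the treated site with a faster wild growth rate, so
suppression metrics have a known direction.

All randomness flows from a single ``numpy`` generator seeded by
``rng_seed``; identical configs produce byte-identical CSV output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .field_data import (
    ReleaseEvent,
    TrapObservation,
    assign_week,
)

__all__ = [
    "COHORT_COLOURS",
    "SimulationConfig",
    "SimulatedTruth",
    "default_release_schedule",
    "simulate_cohort",
    "simulate_trial",
]

COHORT_COLOURS = ("yellow", "blue", "red", "orange")

_TREATED_SITE = "treated"
_CONTROL_SITES = ("control_1", "control_2")


def _monday_of_iso_week(year: int, week: int) -> _dt.date:
    return _dt.date.fromisocalendar(year, week, 1)


def default_release_schedule(
    year: int = 2021,
    first_week: int = 15,
    last_week: int = 41,
    start_per_week: int = 9_000,
    end_per_week: int = 60_000,
    crop_fraction: float = 0.7,
    vial_size: int = 100,
    colour: str = "bulk",
) -> list[ReleaseEvent]:
    """Biweekly (Tue/Fri) release schedule ramping linearly across the season.

    Weekly totals ramp from ``start_per_week`` to ``end_per_week``, split
    evenly over the two release days, ~70% under the crop and the rest on
    the perimeter, each release rounded to whole vials of 100 males. All
    bulk releases share one marker label; the identifiable longevity cohorts
    with rotated powder colours are added by :func:`simulate_trial`, so each
    survival replicate has an uncontaminated recapture window.
    """
    events: list[ReleaseEvent] = []
    n_weeks = last_week - first_week + 1
    for i, week in enumerate(range(first_week, last_week + 1)):
        weekly = start_per_week + (end_per_week - start_per_week) * i / (n_weeks - 1)
        monday = _monday_of_iso_week(year, week)
        for day_offset in (1, 4):  # Tuesday and Friday
            date = monday + _dt.timedelta(days=day_offset)
            per_day = weekly / 2.0
            crop = int(round(per_day * crop_fraction / vial_size)) * vial_size
            perim = int(round(per_day * (1 - crop_fraction) / vial_size)) * vial_size
            events.append(ReleaseEvent(date, _TREATED_SITE, "crop", colour, crop))
            events.append(ReleaseEvent(date, _TREATED_SITE, "perimeter", colour, perim))
    return events


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated trial."""

    pds_true: float = 0.80
    capture_prob: float = 0.02
    release_schedule: Sequence[ReleaseEvent] = field(default_factory=default_release_schedule)
    wild_growth_rate: float = 1.35         # per-week multiplicative factor
    wild_seed_week: int = 27
    wild_seed_size: int = 50
    control_growth_rate: float = 1.5       # wild growth at untreated control sites
    control_seed_size: int = 50
    n_traps: int = 33
    n_excluded_traps: int = 2
    n_control_traps: int = 6
    season_weeks: tuple[int, int] = (15, 41)
    year: int = 2021
    # dedicated longevity (MRR) cohorts released weekly from the first week,
    # each with its own fluorescent-powder label so recapture windows are clean
    n_mrr_cohorts: int = 4
    mrr_cohort_size: int = 5_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pds_true <= 1):
            raise ValueError(f"pds_true must be in (0, 1] (got {self.pds_true})")
        if not (0 <= self.capture_prob < 1):
            raise ValueError(f"capture_prob must be in [0, 1) (got {self.capture_prob})")
        if self.wild_growth_rate < 0:
            raise ValueError("wild_growth_rate must be >= 0")
        if self.n_traps < 1:
            raise ValueError("n_traps must be positive")


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth recorded during simulation, for recovery tests."""

    daily_alive_sterile: dict[_dt.date, int]       # alive at end of day
    weekly_wild_population: dict[int, float]       # treated site
    weekly_wild_population_control: dict[int, float]
    config: SimulationConfig


def simulate_cohort(
    release_size: int,
    pds_true: float,
    capture_prob: float,
    n_days: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Daily recapture counts for one released cohort.

    Cohort-level binomial thinning, exactly equivalent to simulating each
    fly's independent geometric lifetime and daily Bernoulli capture: on each
    day the surviving pool is ``Binomial(n, pds_true)`` of yesterday's pool,
    and ``Binomial(survivors, capture_prob)`` of those are caught and
    removed. Returns an integer array of length ``n_days``.
    """
    if release_size <= 0:
        raise ValueError(f"release_size must be positive (got {release_size})")
    if n_days < 2:
        raise ValueError(f"n_days must be >= 2 (got {n_days})")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    counts = np.zeros(n_days, dtype=int)
    alive = release_size
    for day in range(n_days):
        alive = int(rng.binomial(alive, pds_true)) if pds_true < 1 else alive
        caught = int(rng.binomial(alive, capture_prob)) if capture_prob > 0 else 0
        counts[day] = caught
        alive -= caught
    return counts


def _wild_population(week: int, seed_week: int, seed_size: int, rate: float) -> float:
    if week < seed_week or seed_size == 0:
        return 0.0
    return seed_size * rate ** (week - seed_week)


def simulate_trial(
    config: SimulationConfig,
) -> tuple[list[ReleaseEvent], list[TrapObservation], SimulatedTruth]:
    """Run a full-season simulation of the treated site plus two controls.

    Returns the release log, a daily trap log covering all three sites, and
    the ground truth. Outputs round-trip through the ``field_data`` readers.
    """
    if not config.release_schedule:
        raise ValueError("release_schedule must not be empty")
    rng = np.random.default_rng(config.rng_seed)

    first_week, last_week = config.season_weeks
    start = _monday_of_iso_week(config.year, first_week)
    end = _monday_of_iso_week(config.year, last_week) + _dt.timedelta(days=6)
    n_days = (end - start).days + 1
    days = [start + _dt.timedelta(days=d) for d in range(n_days)]

    all_releases = list(config.release_schedule)
    for i in range(config.n_mrr_cohorts):
        week = first_week + i
        colour = COHORT_COLOURS[i % len(COHORT_COLOURS)]
        date = _monday_of_iso_week(config.year, week) + _dt.timedelta(days=1)  # Tuesday
        all_releases.append(
            ReleaseEvent(date, _TREATED_SITE, "crop", f"mrr_{i + 1}_{colour}", config.mrr_cohort_size)
        )

    releases_by_day: dict[_dt.date, list[ReleaseEvent]] = {}
    for ev in all_releases:
        releases_by_day.setdefault(ev.date, []).append(ev)

    trap_ids = [f"T{i + 1:02d}" for i in range(config.n_traps)]
    # the last n_excluded_traps are flagged out of analysis
    included_flags = [i < config.n_traps - config.n_excluded_traps for i in range(config.n_traps)]

    # cohort pools: colour -> flies alive and uncaptured
    pools: dict[str, int] = {}
    truth_alive: dict[_dt.date, int] = {}
    truth_wild: dict[int, float] = {}
    truth_wild_control: dict[int, float] = {}
    observations: list[TrapObservation] = []

    for date in days:
        for ev in releases_by_day.get(date, ()):
            pools[ev.colour] = pools.get(ev.colour, 0) + ev.count

        day_captures: dict[str, int] = {}
        for colour in list(pools):
            alive = pools[colour]
            if alive == 0:
                continue
            alive = int(rng.binomial(alive, config.pds_true)) if config.pds_true < 1 else alive
            caught = int(rng.binomial(alive, config.capture_prob)) if config.capture_prob > 0 else 0
            pools[colour] = alive - caught
            if caught:
                day_captures[colour] = caught

        week = assign_week(date)
        wild_pop = _wild_population(week, config.wild_seed_week, config.wild_seed_size, config.wild_growth_rate)
        truth_wild[week] = wild_pop
        wild_pop_ctrl = _wild_population(week, config.wild_seed_week, config.control_seed_size, config.control_growth_rate)
        truth_wild_control[week] = wild_pop_ctrl
        truth_alive[date] = sum(pools.values())

        # treated site: spread each colour's captures uniformly over traps
        per_trap_sterile = {
            colour: rng.multinomial(caught, np.full(config.n_traps, 1.0 / config.n_traps))
            for colour, caught in day_captures.items()
        }
        # site-total daily wild captures are Poisson(population x capture_prob),
        # split over traps: equivalently independent per-trap Poissons at mean/n
        wild_m = rng.poisson(wild_pop * config.capture_prob / config.n_traps, size=config.n_traps)
        wild_f = rng.poisson(wild_pop * config.capture_prob / config.n_traps, size=config.n_traps)
        for i, trap in enumerate(trap_ids):
            observations.append(
                TrapObservation(
                    trap_id=trap,
                    site_id=_TREATED_SITE,
                    date_collected=date,
                    days_exposed=1,
                    sterile_counts={c: int(v[i]) for c, v in per_trap_sterile.items() if v[i]},
                    wild_male_count=int(wild_m[i]),
                    wild_female_count=int(wild_f[i]),
                    included_in_analysis=included_flags[i],
                )
            )

        # untreated control sites: wild flies only
        for site in _CONTROL_SITES:
            cm = rng.poisson(wild_pop_ctrl * config.capture_prob / config.n_control_traps, size=config.n_control_traps)
            cf = rng.poisson(wild_pop_ctrl * config.capture_prob / config.n_control_traps, size=config.n_control_traps)
            for j in range(config.n_control_traps):
                observations.append(
                    TrapObservation(
                        trap_id=f"{site}-T{j + 1}",
                        site_id=site,
                        date_collected=date,
                        days_exposed=1,
                        sterile_counts={},
                        wild_male_count=int(cm[j]),
                        wild_female_count=int(cf[j]),
                    )
                )

    truth = SimulatedTruth(
        daily_alive_sterile=truth_alive,
        weekly_wild_population=truth_wild,
        weekly_wild_population_control=truth_wild_control,
        config=config,
    )
    return all_releases, observations, truth
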