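import datetime as dt

import pytest

from sitfield.field_data import ReleaseEvent, TrapObservation
from sitfield.synthetic_field import SimulationConfig, default_release_schedule


def make_trap(
    trap_id="T01",
    site="treated",
    date=dt.date(2021, 4, 12),
    sterile=None,
    wild_m=0,
    wild_f=0,
    included=True,
):
    return TrapObservation(
        trap_id=trap_id,
        site_id=site,
        date_collected=date,
        days_exposed=1,
        sterile_counts=sterile or {},
        wild_male_count=wild_m,
        wild_female_count=wild_f,
        included_in_analysis=included,
    )


@pytest.fixture
def small_config():
    """A short, cheap simulated season: 8 weeks, wild flies from week 18."""
    return SimulationConfig(
        release_schedule=default_release_schedule(first_week=15, last_week=22),
        season_weeks=(15, 22),
        wild_seed_week=18,
        wild_seed_size=200,
        wild_growth_rate=1.4,
        control_seed_size=200,
        control_growth_rate=1.6,
        n_traps=8,
        n_excluded_traps=1,
        n_control_traps=4,
        n_mrr_cohorts=2,
        rng_seed=7,
    )


@pytest.fixture
def release_pair():
    return [
        ReleaseEvent(dt.date(2021, 4, 13), "treated", "crop", "yellow", 619_604),
        ReleaseEvent(dt.date(2021, 4, 13), "treated", "perimeter", "yellow", 331_135),
    ]
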