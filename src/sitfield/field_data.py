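"""Domain records and CSV readers/writers for SIT field-trial logs.

Three tabular inputs drive the pipeline:

* a **release log** — one row per dated release of marked sterile males at a
  site, split by location class (under the crop polytunnels vs the perimeter
  hedgerow) and fluorescent-powder cohort colour;
* a **trap log** — one row per sticky-trap collection, scoring marked sterile
  males by colour alongside wild males and wild females;
* an **assay log** — egg/pupa counts from fecundity–fertility assays.

All files are plain UTF-8 CSV with a mandatory header row. Unknown columns
are ignored on read. Dates are timezone-free ISO-8601 calendar dates; the
trial is daily-resolved, so no finer resolution is needed.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FieldDataError",
    "ReleaseEvent",
    "TrapObservation",
    "AssayRecord",
    "LOCATION_CLASSES",
    "ASSAY_GROUPS",
    "read_release_log",
    "write_release_log",
    "read_trap_log",
    "write_trap_log",
    "read_assay_log",
    "write_assay_log",
    "assign_week",
    "day_index",
]

LOCATION_CLASSES = ("crop", "perimeter")
ASSAY_GROUPS = ("control_nonirradiated", "irradiated", "field_treated", "field_control")

#: fixed (non-colour) columns of the trap CSV schema
_TRAP_FIXED = (
    "trap_id",
    "site_id",
    "date_collected",
    "days_exposed",
    "wild_male",
    "wild_female",
    "included",
)


class FieldDataError(ValueError):
    """Row-level validation failure in a field-trial CSV; names the line."""


def _parse_date(text: str, path: str, line: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError:
        raise FieldDataError(f"{path}:{line}: malformed date {text!r} (expected ISO-8601)") from None


def _parse_count(text: str, path: str, line: int, column: str) -> int:
    text = text.strip()
    if text == "":
        return 0
    try:
        value = int(text)
    except ValueError:
        raise FieldDataError(f"{path}:{line}: non-integer {column} {text!r}") from None
    if value < 0:
        raise FieldDataError(f"{path}:{line}: negative {column} ({value})")
    return value


@dataclass(frozen=True)
class ReleaseEvent:
    """One dated release of ``count`` marked sterile males at a location."""

    date: _dt.date
    site_id: str
    location_class: str
    colour: str
    count: int

    def __post_init__(self) -> None:
        if self.location_class not in LOCATION_CLASSES:
            raise FieldDataError(
                f"unknown location_class {self.location_class!r}; expected one of {LOCATION_CLASSES}"
            )
        if self.count < 0:
            raise FieldDataError(f"negative release count ({self.count})")


@dataclass(frozen=True)
class TrapObservation:
    """One sticky-trap collection: sterile counts by colour plus wild counts.

    Traps excluded from analysis (e.g. traps under differently coloured
    tunnel covers) are carried through with ``included_in_analysis=False``
    rather than dropped, so exclusion stays auditable.
    """

    trap_id: str
    site_id: str
    date_collected: _dt.date
    days_exposed: int
    sterile_counts: Mapping[str, int] = field(default_factory=dict)
    wild_male_count: int = 0
    wild_female_count: int = 0
    included_in_analysis: bool = True

    def __post_init__(self) -> None:
        if self.days_exposed < 1:
            raise FieldDataError(f"days_exposed must be >= 1 (got {self.days_exposed})")
        if self.wild_male_count < 0 or self.wild_female_count < 0:
            raise FieldDataError("negative wild count")
        if any(v < 0 for v in self.sterile_counts.values()):
            raise FieldDataError("negative sterile count")

    @property
    def sterile_total(self) -> int:
        return sum(self.sterile_counts.values())


@dataclass(frozen=True)
class AssayRecord:
    """Egg/pupa outcome for one fecundity–fertility assay vial or group."""

    group: str
    n_females: int
    laying_hours: float
    eggs: int
    pupae: int

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise FieldDataError(f"n_females must be >= 1 (got {self.n_females})")
        if self.laying_hours <= 0:
            raise FieldDataError(f"laying_hours must be > 0 (got {self.laying_hours})")
        if self.eggs < 0 or self.pupae < 0:
            raise FieldDataError("negative egg or pupa count")
        if self.pupae > self.eggs:
            raise FieldDataError(f"pupae ({self.pupae}) exceed eggs ({self.eggs})")


# ---------------------------------------------------------------------------
# calendar utilities


def assign_week(date: _dt.date) -> int:
    """ISO-8601 week number of the given calendar date.

    The trial calendar ("week 15" … "week 41") follows ISO weeks, which for
    2021 place mid-April in week 15 and mid-October in week 41.
    """
    return date.isocalendar()[1]


def day_index(date: _dt.date, origin: _dt.date) -> int:
    """1-based day index of ``date`` relative to ``origin`` (origin -> 1)."""
    return (date - origin).days + 1


# ---------------------------------------------------------------------------
# release log


def read_release_log(path: str | Path) -> list[ReleaseEvent]:
    """Read a release log CSV into :class:`ReleaseEvent` records.

    Schema: ``date,site_id,location_class,colour,count``. Rows with count 0
    are retained (a scheduled release that did not happen is still a record).
    Validation failures raise :class:`FieldDataError` naming the line number.
    """
    path = Path(path)
    events: list[ReleaseEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "date" not in reader.fieldnames:
            raise FieldDataError(f"{path}: missing header row with a 'date' column")
        for line, row in enumerate(reader, start=2):
            date = _parse_date(row["date"], str(path), line)
            count = _parse_count(row.get("count", ""), str(path), line, "count")
            loc = (row.get("location_class") or "").strip()
            if loc not in LOCATION_CLASSES:
                raise FieldDataError(
                    f"{path}:{line}: unknown location_class {loc!r}; expected one of {LOCATION_CLASSES}"
                )
            events.append(
                ReleaseEvent(
                    date=date,
                    site_id=(row.get("site_id") or "").strip(),
                    location_class=loc,
                    colour=(row.get("colour") or "").strip(),
                    count=count,
                )
            )
    return events


def write_release_log(events: Iterable[ReleaseEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "site_id", "location_class", "colour", "count"])
        for ev in events:
            writer.writerow([ev.date.isoformat(), ev.site_id, ev.location_class, ev.colour, ev.count])


# ---------------------------------------------------------------------------
# trap log


def read_trap_log(path: str | Path) -> list[TrapObservation]:
    """Read a trap log CSV into :class:`TrapObservation` records.

    Schema: ``trap_id,site_id,date_collected,days_exposed,wild_male,
    wild_female,included,<one column per cohort colour>``. Any column not in
    the fixed set is treated as a cohort-colour count; a missing colour
    column is a zero. Duplicate (trap_id, date_collected) rows are an error.
    """
    path = Path(path)
    observations: list[TrapObservation] = []
    seen: set[tuple[str, _dt.date]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "trap_id" not in reader.fieldnames:
            raise FieldDataError(f"{path}: missing header row with a 'trap_id' column")
        colour_cols = [c for c in reader.fieldnames if c not in _TRAP_FIXED]
        for line, row in enumerate(reader, start=2):
            trap_id = (row.get("trap_id") or "").strip()
            date = _parse_date(row["date_collected"], str(path), line)
            key = (trap_id, date)
            if key in seen:
                raise FieldDataError(
                    f"{path}:{line}: duplicate record for trap {trap_id!r} on {date.isoformat()}"
                )
            seen.add(key)
            days_exposed = _parse_count(row.get("days_exposed", "1") or "1", str(path), line, "days_exposed")
            if days_exposed < 1:
                raise FieldDataError(f"{path}:{line}: days_exposed must be >= 1 (got {days_exposed})")
            included_raw = (row.get("included") or "true").strip().lower()
            included = included_raw not in ("false", "0", "no")
            sterile = {
                colour: _parse_count(row.get(colour, "") or "", str(path), line, colour)
                for colour in colour_cols
            }
            observations.append(
                TrapObservation(
                    trap_id=trap_id,
                    site_id=(row.get("site_id") or "").strip(),
                    date_collected=date,
                    days_exposed=days_exposed,
                    sterile_counts=sterile,
                    wild_male_count=_parse_count(row.get("wild_male", "") or "", str(path), line, "wild_male"),
                    wild_female_count=_parse_count(row.get("wild_female", "") or "", str(path), line, "wild_female"),
                    included_in_analysis=included,
                )
            )
    return observations


def write_trap_log(observations: Sequence[TrapObservation], path: str | Path) -> None:
    path = Path(path)
    colours = sorted({c for obs in observations for c in obs.sterile_counts})
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_TRAP_FIXED) + colours)
        for obs in observations:
            writer.writerow(
                [
                    obs.trap_id,
                    obs.site_id,
                    obs.date_collected.isoformat(),
                    obs.days_exposed,
                    obs.wild_male_count,
                    obs.wild_female_count,
                    "true" if obs.included_in_analysis else "false",
                ]
                + [obs.sterile_counts.get(c, 0) for c in colours]
            )


# ---------------------------------------------------------------------------
# assay log


def read_assay_log(path: str | Path) -> list[AssayRecord]:
    """Read an assay log CSV (``group,n_females,laying_hours,eggs,pupae``)."""
    path = Path(path)
    records: list[AssayRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "group" not in reader.fieldnames:
            raise FieldDataError(f"{path}: missing header row with a 'group' column")
        for line, row in enumerate(reader, start=2):
            try:
                records.append(
                    AssayRecord(
                        group=(row.get("group") or "").strip(),
                        n_females=int(row["n_females"]),
                        laying_hours=float(row["laying_hours"]),
                        eggs=_parse_count(row.get("eggs", ""), str(path), line, "eggs"),
                        pupae=_parse_count(row.get("pupae", ""), str(path), line, "pupae"),
                    )
                )
            except FieldDataError as exc:
                if str(path) in str(exc):
                    raise
                raise FieldDataError(f"{path}:{line}: {exc}") from None
            except (KeyError, ValueError) as exc:
                raise FieldDataError(f"{path}:{line}: {exc}") from None
    return records


def write_assay_log(records: Iterable[AssayRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "n_females", "laying_hours", "eggs", "pupae"])
        for rec in records:
            writer.writerow([rec.group, rec.n_females, rec.laying_hours, rec.eggs, rec.pupae])
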