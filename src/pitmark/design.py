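"""Sampling design: occasion calendar, staggered release cohorts, seasons.

The study design is a sequence of K sampling occasions with known calendar
dates and cohort ages (months).  Inter-occasion intervals are measured in
months and are unequal; survival over an interval is the monthly rate raised
to the interval length.  Each occasion and each interval carries a season
label: summer (June-October, the fast-growth season) or winter
(October-May).  October appears in both season definitions, so by
convention occasions *dated* in October are summer occasions while interval
months from October onward count toward winter, which puts an interval
*starting* in October into winter.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass

import numpy as np

SUMMER = 1
WINTER = 2

SEASON_NAMES = {SUMMER: "summer", WINTER: "winter"}

# Occasions dated June-October are summer sampling events.
_OCCASION_SUMMER_MONTHS = frozenset({6, 7, 8, 9, 10})
# When classifying the months an interval spans, October counts toward
# winter (winter runs October to May).
_INTERVAL_SUMMER_MONTHS = frozenset({6, 7, 8, 9})

_SEASON_RULES = ("majority", "start", "terminal")


class DesignError(ValueError):
    """Inconsistent sampling design (non-monotone dates/ages, bad labels)."""


def occasion_season(date: _dt.date) -> int:
    """Season label of a sampling occasion from its calendar month."""
    return SUMMER if date.month in _OCCASION_SUMMER_MONTHS else WINTER


def _months_spanned(start: _dt.date, end: _dt.date) -> list[int]:
    """Calendar months covered by the interval [start, end).

    Months are enumerated from the start month up to (but excluding) the
    month of the terminal occasion; a within-month interval yields just the
    start month.
    """
    months = []
    y, m = start.year, start.month
    while (y, m) < (end.year, end.month):
        months.append(m)
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return months or [start.month]


def interval_season(start: _dt.date, end: _dt.date, rule: str = "majority") -> int:
    """Season label of the interval between two adjacent occasions.

    ``majority`` (default): the season holding the majority of calendar
    months spanned by the interval, with October-May counting as winter;
    ties go to the season of the terminal occasion.  ``start`` /
    ``terminal`` label the interval by the bracketing occasion instead.
    """
    if rule not in _SEASON_RULES:
        raise ValueError(f"unknown season rule {rule!r}; choose from {_SEASON_RULES}")
    if rule == "start":
        # an interval beginning in October belongs to winter
        return SUMMER if start.month in _INTERVAL_SUMMER_MONTHS else WINTER
    if rule == "terminal":
        return occasion_season(end)
    months = _months_spanned(start, end)
    n_summer = sum(m in _INTERVAL_SUMMER_MONTHS for m in months)
    n_winter = len(months) - n_summer
    if n_summer > n_winter:
        return SUMMER
    if n_winter > n_summer:
        return WINTER
    return occasion_season(end)


@dataclass(frozen=True)
class OccasionCalendar:
    """Dates, ages and seasons of the K sampling occasions.

    ``delta_t`` (K-1 entries, months) is derived from the cohort-age row,
    not recomputed from calendar dates, so it matches the design table
    exactly.  ``interval_season[k]`` labels the interval ending at occasion
    k+1.
    """

    dates: tuple[_dt.date, ...]
    ages_months: np.ndarray
    delta_t: np.ndarray
    occasion_season: np.ndarray
    interval_season: np.ndarray
    season_rule: str = "majority"

    def __post_init__(self):
        object.__setattr__(self, "ages_months", np.asarray(self.ages_months, float))
        object.__setattr__(self, "delta_t", np.asarray(self.delta_t, float))
        object.__setattr__(self, "occasion_season", np.asarray(self.occasion_season, int))
        object.__setattr__(self, "interval_season", np.asarray(self.interval_season, int))
        k = len(self.dates)
        if self.ages_months.shape != (k,):
            raise DesignError("ages_months length does not match dates")
        if self.delta_t.shape != (k - 1,) or self.interval_season.shape != (k - 1,):
            raise DesignError("interval arrays must have K-1 entries")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise DesignError("occasion dates must be strictly increasing")
        if np.any(self.delta_t <= 0):
            raise DesignError("delta_t must be positive (ages strictly increasing)")
        for lab in np.concatenate([self.occasion_season, self.interval_season]):
            if lab not in (SUMMER, WINTER):
                raise DesignError(f"season label {lab} outside {{1, 2}}")

    @property
    def n_occasions(self) -> int:
        return len(self.dates)

    @property
    def span_months(self) -> float:
        """Total study span, equals ages_months[-1] - ages_months[0]."""
        return float(self.delta_t.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "occasion": np.arange(1, self.n_occasions + 1),
                "date": [d.isoformat() for d in self.dates],
                "age_months": self.ages_months,
                "season": self.occasion_season,
            }
        )


def build_calendar(dates, ages_months, season_rule: str = "majority") -> OccasionCalendar:
    """Build an :class:`OccasionCalendar` from dates and cohort ages.

    Parameters
    ----------
    dates
        Ordered calendar dates (datetime.date or ISO-8601 strings), one per
        sampling occasion.
    ages_months
        Cohort age in months at each occasion; interval lengths ``delta_t``
        are successive differences of this row.
    season_rule
        How intervals spanning both seasons are labelled (see
        :func:`interval_season`).
    """
    parsed = tuple(
        d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d)) for d in dates
    )
    ages = np.asarray(ages_months, float)
    if len(parsed) != ages.size:
        raise ValueError("dates and ages_months must have equal length")
    if len(parsed) < 2:
        raise DesignError("a calendar needs at least two occasions")
    if any(b <= a for a, b in zip(parsed, parsed[1:])):
        raise DesignError("occasion dates must be strictly increasing")
    delta = np.diff(ages)
    if np.any(delta <= 0):
        raise DesignError("ages_months must be strictly increasing")
    occ = np.array([occasion_season(d) for d in parsed])
    ints = np.array(
        [interval_season(a, b, season_rule) for a, b in zip(parsed, parsed[1:])]
    )
    return OccasionCalendar(parsed, ages, delta, occ, ints, season_rule)


@dataclass(frozen=True)
class CohortTable:
    """Staggered release cohorts: occasion index (0-based) and size each."""

    release_occasion: np.ndarray
    cohort_size: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "release_occasion", np.asarray(self.release_occasion, int))
        object.__setattr__(self, "cohort_size", np.asarray(self.cohort_size, int))
        if self.release_occasion.shape != self.cohort_size.shape:
            raise DesignError("cohort arrays must have equal length")
        if np.any(self.cohort_size < 0):
            raise DesignError("cohort sizes must be non-negative")
        if np.any(self.release_occasion < 0):
            raise DesignError("release occasions must be valid calendar indices")

    @property
    def n_individuals(self) -> int:
        return int(self.cohort_size.sum())

    def releases_per_occasion(self, n_occasions: int) -> np.ndarray:
        if np.any(self.release_occasion >= n_occasions):
            raise DesignError("release occasion beyond calendar")
        out = np.zeros(n_occasions, int)
        np.add.at(out, self.release_occasion, self.cohort_size)
        return out


# The Powell River (TN) release design: five cohorts of laboratory-reared
# juveniles released at the first five of eight sampling occasions.
_STUDY_DATES = (
    "2009-07-01",
    "2009-08-26",
    "2009-10-07",
    "2010-06-25",
    "2010-10-11",
    "2011-05-10",
    "2011-08-17",
    "2011-10-12",
)
_STUDY_AGES = (24.5, 26.5, 28.0, 36.5, 40.0, 47.0, 50.0, 52.0)
_STUDY_COHORT_SIZES = (23, 28, 38, 9, 1)


def powell_river_design(season_rule: str = "majority") -> tuple[OccasionCalendar, CohortTable]:
    """The eight-occasion Powell River study design.

    Five cohorts (23, 28, 38, 9 and 1 mussels) entered at the first five
    occasions; the calendar spans 27.5 months with interval lengths
    (2, 1.5, 8.5, 3.5, 7, 3, 2) months.
    """
    cal = build_calendar(_STUDY_DATES, _STUDY_AGES, season_rule)
    cohorts = CohortTable(np.arange(5), np.array(_STUDY_COHORT_SIZES))
    return cal, cohorts


def write_calendar(calendar: OccasionCalendar, path) -> None:
    """Write the calendar as a small CSV (occasion, date, age_months, season)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["occasion", "date", "age_months", "season"])
        for i, (d, a, s) in enumerate(
            zip(calendar.dates, calendar.ages_months, calendar.occasion_season), start=1
        ):
            w.writerow([i, d.isoformat(), a, int(s)])


def read_calendar(path, season_rule: str = "majority") -> OccasionCalendar:
    """Read a calendar CSV written by :func:`write_calendar`.

    Interval lengths and interval seasons are recomputed from the age row
    and the season rule; the stored occasion seasons are validated against
    the dates.
    """
    dates, ages, seasons = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dates.append(row["date"])
            ages.append(float(row["age_months"]))
            seasons.append(int(row["season"]))
    cal = build_calendar(dates, ages, season_rule)
    if list(cal.occasion_season) != seasons:
        raise DesignError("stored occasion seasons disagree with occasion dates")
    return cal
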