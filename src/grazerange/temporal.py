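"""Temporal context for GPS fixes: treatment windows, seasons, filters.

The analysis this package supports contrasts animal behaviour across 21-day
windows anchored on livestock grazing terms: the 21 days *before* a term
starts, days 1-21 (*early*) and days 22-42 (*ongoing*) of the term, and the
21 days *after* it ends.  Everything else is *unassigned* and excluded from
modelling.  Windows are defined on local calendar dates (fixed UTC offset),
because "21 days" is calendar language, not 24-hour arithmetic.

A grazing term shorter than 42 days yields no *ongoing* window: labelling a
handful of leftover days as a category of their own would create an unusable
factor level, and short-term replicas are expected to feature only three
treatment levels.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_DAYS = 21
HUNT_EXCLUSION_DAYS = 6  # a hunt day plus the following six days are dropped

TREATMENT_LEVELS = ("before", "early", "ongoing", "after", "unassigned")


@dataclass
class GrazingSchedule:
    """Grazing-site polygons plus dated grazing intervals.

    Attributes
    ----------
    intervals : pandas.DataFrame
        Columns ``site_id, group, start, end``; ``start``/``end`` are
        inclusive calendar dates (datetime.date).
    site_polygons : dict
        site_id -> shapely Polygon (planar meters).
    site_groups : dict
        site_id -> group label (e.g. ``north`` / ``south``).
    """

    intervals: pd.DataFrame
    site_polygons: dict = field(default_factory=dict)
    site_groups: dict = field(default_factory=dict)

    def groups(self) -> list[str]:
        return sorted(self.intervals["group"].unique())

    def intervals_for(self, group: str) -> pd.DataFrame:
        sub = self.intervals[self.intervals["group"] == group]
        return sub.sort_values("start").reset_index(drop=True)

    def validate(self) -> None:
        """Raise if grazing intervals within any one group overlap."""
        for group in self.groups():
            sub = self.intervals_for(group)
            prev_end = None
            for _, row in sub.iterrows():
                if row["end"] < row["start"]:
                    raise ValueError(f"interval ends before it starts: {row.to_dict()}")
                if prev_end is not None and row["start"] <= prev_end:
                    raise ValueError(
                        f"overlapping grazing intervals in group {group!r}"
                    )
                prev_end = row["end"]

    def polygons_for_group(self, group: str):
        return [
            poly
            for sid, poly in self.site_polygons.items()
            if self.site_groups.get(sid) == group
        ]

    def to_csv(self, path) -> None:
        self.intervals.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_polygons=None, site_groups=None) -> "GrazingSchedule":
        df = pd.read_csv(path)
        df["start"] = pd.to_datetime(df["start"]).dt.date
        df["end"] = pd.to_datetime(df["end"]).dt.date
        return cls(df, site_polygons or {}, site_groups or {})


# ---------------------------------------------------------------------------
# helpers


def _local_dates(timestamps, utc_offset_hours: float) -> np.ndarray:
    """Proleptic-Gregorian ordinals of the local calendar date of each fix."""
    ts = pd.to_datetime(pd.Series(timestamps))
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    local = ts.dt.tz_convert("UTC") + pd.Timedelta(hours=utc_offset_hours)
    # ordinal = days since 0001-01-01 + 1; floor the datetime to a date
    return np.asarray(local.dt.normalize().map(pd.Timestamp.toordinal), dtype=int)


def _date_range_ordinals(first: dt.date, last: dt.date) -> np.ndarray:
    """Inclusive range of date ordinals."""
    return np.arange(first.toordinal(), last.toordinal() + 1)


# ---------------------------------------------------------------------------
# operations


def assign_treatment(timestamps, schedule: GrazingSchedule, group: str,
                     utc_offset_hours: float = 1.0) -> pd.Series:
    """Label fixes with the 21-day treatment window relative to grazing terms.

    Parameters
    ----------
    timestamps : sequence of datetimes (UTC)
    schedule : GrazingSchedule
    group : str
        Site group whose grazing terms anchor the windows (the group
        overlapping the animal's home range).
    utc_offset_hours : float
        Fixed offset defining the local calendar day (default +1, central
        European winter time).

    Returns
    -------
    pandas.Series of {'before','early','ongoing','after','unassigned'}.

    Notes
    -----
    When windows from consecutive terms collide, within-term labels win over
    before/after, and among the rest the first term (chronological) wins.
    """
    sub = schedule.intervals_for(group)
    if len(sub) == 0:
        raise ValueError(f"schedule has no intervals for group {group!r}")
    schedule.validate()

    label_days: dict[str, set] = {k: set() for k in ("early", "ongoing", "before", "after")}
    day = dt.timedelta(days=1)
    for _, row in sub.iterrows():
        start, end = row["start"], row["end"]
        term_days = (end - start).days + 1
        label_days["early"].update(
            _date_range_ordinals(start, min(end, start + dt.timedelta(days=WINDOW_DAYS - 1)))
        )
        if term_days >= 2 * WINDOW_DAYS:
            label_days["ongoing"].update(
                _date_range_ordinals(
                    start + dt.timedelta(days=WINDOW_DAYS),
                    min(end, start + dt.timedelta(days=2 * WINDOW_DAYS - 1)),
                )
            )
        label_days["before"].update(
            _date_range_ordinals(start - dt.timedelta(days=WINDOW_DAYS), start - day)
        )
        label_days["after"].update(
            _date_range_ordinals(end + day, end + dt.timedelta(days=WINDOW_DAYS))
        )

    ordinals = _local_dates(timestamps, utc_offset_hours)
    out = np.full(len(ordinals), "unassigned", dtype=object)
    # precedence: within-term labels first, then before, then after
    for label in ("early", "ongoing", "before", "after"):
        days = np.fromiter(label_days[label], dtype=int) if label_days[label] else np.empty(0, int)
        mask = (out == "unassigned") & np.isin(ordinals, days)
        out[mask] = label
    return pd.Series(out, index=pd.RangeIndex(len(out)), name="treatment")


def exclude_hunt_windows(relocations: pd.DataFrame, hunt_dates,
                         utc_offset_hours: float = 1.0,
                         timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Drop fixes recorded on a driven-hunt day or the following six days.

    Overlapping exclusion windows are unioned, so no fix is double counted
    and applying the filter twice is a no-op.
    """
    if len(relocations) == 0 or not len(list(hunt_dates)):
        return relocations.copy()
    excluded: set[int] = set()
    for h in hunt_dates:
        h = pd.Timestamp(h).date()
        excluded.update(
            _date_range_ordinals(h, h + dt.timedelta(days=HUNT_EXCLUSION_DAYS))
        )
    ordinals = _local_dates(relocations[timestamp_col], utc_offset_hours)
    keep = ~np.isin(ordinals, np.fromiter(excluded, dtype=int))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("hunt-window exclusion dropped %d fixes", n_dropped)
    return relocations.loc[keep].reset_index(drop=True)


def flag_biological_periods(timestamps, sex) -> pd.DataFrame:
    """Calving and rutting-period flags for each fix.

    calving: date in [May 15, Jun 15] and the animal is female;
    rut:     date in [Sep 1, Oct 15] regardless of sex.
    """
    ts = pd.to_datetime(pd.Series(timestamps))
    month, dayofmonth = ts.dt.month.values, ts.dt.day.values
    sex_arr = np.asarray(pd.Series(sex).astype(str).str.lower())
    in_calving = ((month == 5) & (dayofmonth >= 15)) | ((month == 6) & (dayofmonth <= 15))
    calving = in_calving & (sex_arr == "female")
    rut = (month == 9) | ((month == 10) & (dayofmonth <= 15))
    return pd.DataFrame({"calving": calving, "rut": rut})


def assign_season(timestamps) -> pd.Series:
    """May-October -> summer; November-January -> winter; otherwise excluded."""
    ts = pd.to_datetime(pd.Series(timestamps))
    month = ts.dt.month.values
    out = np.full(len(month), "excluded", dtype=object)
    out[(month >= 5) & (month <= 10)] = "summer"
    out[(month >= 11) | (month == 1)] = "winter"
    return pd.Series(out, name="season")


def assign_site_group(home_polygon, schedule: GrazingSchedule):
    """Site group whose polygons the home range overlaps.

    Ties are resolved toward the larger intersection area.  Returns ``None``
    (with a logged warning) when the home range misses every site: such an
    animal carries no information about the grazing treatment and is dropped.
    """
    if home_polygon is None or home_polygon.is_empty or not home_polygon.is_valid:
        raise ValueError("invalid home polygon")
    best_group, best_area = None, 0.0
    groups = sorted(set(schedule.site_groups.values()))
    for group in groups:
        area = sum(
            home_polygon.intersection(p).area for p in schedule.polygons_for_group(group)
        )
        if area > best_area:
            best_group, best_area = group, area
    if best_group is None:
        logger.warning("home range overlaps no grazing site; animal unassignable")
    return best_group
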