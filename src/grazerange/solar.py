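"""Solar event times and day/night/twilight classification.

Sunrise and sunset are defined at a solar elevation of -0.833 deg (standard
refraction plus solar radius), nautical dawn/dusk at -12 deg.  Times come from
the NOAA low-accuracy solar position algorithm (declination and equation of
time from the fractional year), which is accurate to well under a minute at
mid-latitudes -- far below the 2-hour cadence of the telemetry this package
deals with.

A single study-area reference coordinate is used for all fixes: the study
areas targeted here span well under a fifth of a degree, so per-fix solar
geometry would change event times by seconds.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from functools import lru_cache

RISE_SET_ELEV = -0.833  # degrees
NAUTICAL_ELEV = -12.0


@dataclass
class SolarEvents:
    """UTC instants of the four solar events on one calendar day.

    Any event may be ``None`` when the sun never crosses the corresponding
    elevation (polar day/night, or bright nautical nights in high summer).
    """

    date: dt.date
    sunrise: dt.datetime | None
    sunset: dt.datetime | None
    nautical_dawn: dt.datetime | None
    nautical_dusk: dt.datetime | None


def _frac_year(day_of_year: int, hour: float) -> float:
    return 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour - 12) / 24.0)


def _decl_eqtime(gamma: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes)."""
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return decl, eqtime


def _hour_angle(lat_deg: float, decl: float, elev_deg: float) -> float | None:
    """Hour angle (degrees, positive) at which the sun sits at ``elev_deg``."""
    lat = math.radians(lat_deg)
    elev = math.radians(elev_deg)
    cos_ha = (math.sin(elev) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        return None
    return math.degrees(math.acos(cos_ha))


@lru_cache(maxsize=8192)
def solar_events(date: dt.date, lat: float, lon: float) -> SolarEvents:
    """Compute sunrise/sunset and nautical dawn/dusk (UTC) for one day.

    Parameters
    ----------
    date : datetime.date
        Calendar day (interpreted in UTC).
    lat, lon : float
        Geographic coordinates in degrees; east and north positive.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude out of range: {lon}")

    doy = date.timetuple().tm_yday
    gamma = _frac_year(doy, 12.0)
    decl, eqtime = _decl_eqtime(gamma)
    # solar noon in minutes after UTC midnight
    noon_min = 720.0 - 4.0 * lon - eqtime

    def _event(elev: float, sign: int) -> dt.datetime | None:
        ha = _hour_angle(lat, decl, elev)
        if ha is None:
            return None
        minutes = noon_min - sign * 4.0 * ha  # sign +1 -> morning event
        base = dt.datetime.combine(date, dt.time(), tzinfo=dt.timezone.utc)
        return base + dt.timedelta(minutes=minutes)

    return SolarEvents(
        date=date,
        sunrise=_event(RISE_SET_ELEV, +1),
        sunset=_event(RISE_SET_ELEV, -1),
        nautical_dawn=_event(NAUTICAL_ELEV, +1),
        nautical_dusk=_event(NAUTICAL_ELEV, -1),
    )


def solar_elevation(when: dt.datetime, lat: float, lon: float) -> float:
    """Solar elevation angle in degrees at a UTC instant (NOAA formulas)."""
    if when.tzinfo is None:
        when = when.replace(tzinfo=dt.timezone.utc)
    when = when.astimezone(dt.timezone.utc)
    doy = when.timetuple().tm_yday
    hour = when.hour + when.minute / 60.0 + when.second / 3600.0
    gamma = _frac_year(doy, hour)
    decl, eqtime = _decl_eqtime(gamma)
    tst = hour * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)
    lat_r = math.radians(lat)
    cos_zen = math.sin(lat_r) * math.sin(decl) + math.cos(lat_r) * math.cos(
        decl
    ) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


def classify_time_of_day(when: dt.datetime, lat: float, lon: float) -> str:
    """Classify a UTC instant as ``day``, ``night`` or ``twilight``.

    day      = [sunrise, sunset)
    twilight = [nautical_dawn, sunrise) | [sunset, nautical_dusk)
    night    = everything else

    Intervals are half-open so the three classes partition the day; a fix at
    an exact event instant goes to the later class.
    """
    if when.tzinfo is None:
        when = when.replace(tzinfo=dt.timezone.utc)
    when = when.astimezone(dt.timezone.utc)
    ev = solar_events(when.date(), lat, lon)
    if ev.sunrise is not None and ev.sunset is not None:
        if ev.sunrise <= when < ev.sunset:
            return "day"
    elif solar_elevation(when, lat, lon) >= RISE_SET_ELEV:
        return "day"  # polar day
    if ev.nautical_dawn is not None and ev.sunrise is not None:
        if ev.nautical_dawn <= when < ev.sunrise:
            return "twilight"
    if ev.sunset is not None and ev.nautical_dusk is not None:
        if ev.sunset <= when < ev.nautical_dusk:
            return "twilight"
    if ev.nautical_dawn is None or ev.nautical_dusk is None:  # noqa: SIM102
        # sun never crosses -12 deg: non-day hours are twilight (bright
        # summer nights) or, with no sunrise at all, polar twilight/night
        if solar_elevation(when, lat, lon) >= NAUTICAL_ELEV:
            return "twilight"
    return "night"


def classify_times(timestamps, lat: float, lon: float) -> list[str]:
    """Vector version of :func:`classify_time_of_day` (events cached per day)."""
    import pandas as pd

    ts = pd.to_datetime(pd.Series(timestamps))
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    ts = ts.dt.tz_convert("UTC")
    return [classify_time_of_day(t.to_pydatetime(), lat, lon) for t in ts]
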