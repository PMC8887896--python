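"""Solar position and astronomical-twilight times.

Implements the NOAA solar-position equations (Meeus-derived, as used in the
NOAA solar calculator). Accuracy of the elevation angle is ~0.01 deg, giving
twilight-crossing times good to well under a minute at tropical latitudes.

Astronomical twilight boundaries are the times at which the geometric solar
elevation crosses -18 deg: the *end* of evening astronomical twilight (sun
sinking through -18 deg after sunset) and the *start* of morning astronomical
twilight (sun rising through -18 deg before sunrise). These anchor the timing
of sleep onset and awakening in nocturnal-sleep analyses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

ASTRO_TWILIGHT_DEG = -18.0


def _julian_day(t: dt.datetime) -> float:
    """Julian day number for a UTC datetime."""
    if t.tzinfo is not None:
        t = t.astimezone(dt.timezone.utc).replace(tzinfo=None)
    y, m = t.year, t.month
    d = (
        t.day
        + t.hour / 24.0
        + t.minute / 1440.0
        + (t.second + t.microsecond / 1e6) / 86400.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def solar_elevation(t_utc: dt.datetime, lat: float, lon: float) -> float:
    """Geometric solar elevation angle (degrees, no refraction) at a UTC time.

    Parameters
    ----------
    t_utc : datetime
        Time; naive datetimes are taken as UTC.
    lat, lon : float
        Site latitude (north positive) and longitude (east positive), degrees.
    """
    jd = _julian_day(t_utc)
    T = (jd - 2451545.0) / 36525.0

    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.deg2rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(np.deg2rad(omega))

    decl = np.rad2deg(np.arcsin(np.sin(np.deg2rad(eps)) * np.sin(np.deg2rad(app_long))))

    # Equation of time, minutes
    y = np.tan(np.deg2rad(eps / 2.0)) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2 * e * np.sin(Mr)
        + 4 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )

    if t_utc.tzinfo is not None:
        t_utc = t_utc.astimezone(dt.timezone.utc).replace(tzinfo=None)
    minutes_utc = t_utc.hour * 60 + t_utc.minute + t_utc.second / 60.0
    tst = (minutes_utc + eot + 4.0 * lon) % 1440.0
    ha = tst / 4.0 - 180.0 if tst / 4.0 >= 0 else tst / 4.0 + 180.0

    latr = np.deg2rad(lat)
    declr = np.deg2rad(decl)
    har = np.deg2rad(ha)
    elev = np.arcsin(
        np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(har)
    )
    return float(np.rad2deg(elev))


@dataclass(frozen=True)
class TwilightTimes:
    """Astronomical-twilight boundaries for one local date."""

    date: dt.date
    morning_astro_start: dt.datetime  # sun rising through -18 deg
    evening_astro_end: dt.datetime  # sun sinking through -18 deg


def _crossing(
    day_start: dt.datetime,
    lat: float,
    lon: float,
    search_min: tuple[int, int],
    rising: bool,
    angle: float,
) -> dt.datetime:
    """Find the minute-interpolated time the elevation crosses `angle`."""
    lo, hi = search_min
    minutes = np.arange(lo, hi + 1)
    elev = np.array(
        [solar_elevation(day_start + dt.timedelta(minutes=int(m)), lat, lon) for m in minutes]
    )
    above = elev > angle
    if rising:
        idx = np.nonzero(~above[:-1] & above[1:])[0]
    else:
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if len(idx) == 0:
        raise ValueError(
            f"no {'rising' if rising else 'setting'} crossing of {angle} deg "
            f"in search window; twilight undefined at lat={lat}, date={day_start.date()}"
        )
    i = int(idx[0])
    e0, e1 = elev[i], elev[i + 1]
    frac = (angle - e0) / (e1 - e0)
    return day_start + dt.timedelta(minutes=float(minutes[i]) + float(frac))


def compute_twilight(
    date: dt.date, lat: float, lon: float, tz: dt.tzinfo
) -> TwilightTimes:
    """Astronomical-twilight boundary times for a local calendar date.

    Raises ``ValueError`` when the sun never reaches -18 deg on that date
    (high latitudes in summer).
    """
    day_start = dt.datetime(date.year, date.month, date.day, tzinfo=tz)
    morning = _crossing(day_start, lat, lon, (0, 10 * 60), rising=True, angle=ASTRO_TWILIGHT_DEG)
    evening = _crossing(
        day_start, lat, lon, (14 * 60, 24 * 60 - 1), rising=False, angle=ASTRO_TWILIGHT_DEG
    )
    return TwilightTimes(date=date, morning_astro_start=morning, evening_astro_end=evening)


def compute_sun_crossing(
    date: dt.date, lat: float, lon: float, tz: dt.tzinfo, angle: float, rising: bool
) -> dt.datetime:
    """Time the sun crosses an arbitrary elevation angle on a local date."""
    day_start = dt.datetime(date.year, date.month, date.day, tzinfo=tz)
    window = (0, 12 * 60) if rising else (12 * 60, 24 * 60 - 1)
    return _crossing(day_start, lat, lon, window, rising=rising, angle=angle)
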