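"""Climate-window covariates and the topographic solar index.

Weather enters the individual torpor model at four temporal scales: the
observation day itself ("daily"), and the 7, 30 and 90 days preceding and
including it ("weekly", "monthly", "seasonal").  Temperature windows are
means of the daily minimum; rainfall windows are totals.  Each summary is
expressed as a residual from a 30-year day-of-year baseline aggregated over
the same window, so positive values mean warmer/wetter than usual for that
time of year.

The solar index measures the proportion of direct solar beam a tilted
ground surface receives: 0 in full shade (sun below the horizon), 1 when
the beam is perpendicular to the surface.  It is computed at 12:00 solar
time on the first day of each month and averaged over the twelve months.
The beam is treated as unobstructed (no terrain horizon shading) and solar
time is used directly, without a longitude or equation-of-time correction:
the index serves as a relative site descriptor, not an irradiance model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "WINDOW_DAYS",
    "window_summaries",
    "solar_declination",
    "solar_position",
    "solar_index",
]

#: window lengths in days, ending on and including the observation date
WINDOW_DAYS = {"daily": 1, "weekly": 7, "monthly": 30, "seasonal": 90}

#: first day of each month as a day-of-year on a non-leap calendar
_MONTH_START_DOY = (1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335)


def _baseline_daily(baseline: pd.DataFrame, dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Expand a day-of-year climatology onto concrete dates (Feb 29 -> day 59)."""
    if "day_of_year" not in baseline.columns:
        raise ValueError("baseline table needs a 'day_of_year' column")
    clim = baseline.set_index("day_of_year")
    doy = np.asarray(dates.dayofyear).copy()
    leap = np.asarray(dates.is_leap_year)
    doy[leap & (doy >= 60)] -= 1  # map onto a 365-day climatology
    out = clim.reindex(doy).reset_index(drop=True)
    out.index = dates
    return out


def window_summaries(weather: pd.DataFrame, baseline: pd.DataFrame,
                     obs: pd.DataFrame) -> pd.DataFrame:
    """Multi-window weather residuals for each observation.

    Parameters
    ----------
    weather : DataFrame
        Daily site weather with columns ``site_id, date, tmin_c, rain_mm``.
    baseline : DataFrame
        Day-of-year climatology with columns ``day_of_year, tmin_c, rain_mm``.
    obs : DataFrame
        Observations with ``site_id`` and ``date``; the returned frame is
        aligned to its index.

    Returns
    -------
    DataFrame with columns ``tmin_<w>_resid`` (deg C, window mean minus
    baseline window mean) and ``rain_<w>_resid`` (mm, window total minus
    baseline window total) for w in daily/weekly/monthly/seasonal.

    Raises
    ------
    ValueError
        If any observation lacks the 90 days of weather history ending on
        its date; the error names the first offending observation.
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    obs_dates = pd.to_datetime(obs["date"])

    full_range = pd.date_range(weather["date"].min(), weather["date"].max(), freq="D")
    base_daily = _baseline_daily(baseline, full_range)

    pieces = {}
    for var, stat in (("tmin_c", "mean"), ("rain_mm", "sum")):
        wide = weather.pivot_table(index="date", columns="site_id", values=var,
                                   aggfunc="first")
        wide = wide.reindex(full_range)
        bseries = base_daily[var]
        for wname, wdays in WINDOW_DAYS.items():
            roll = wide.rolling(wdays, min_periods=wdays)
            broll = bseries.rolling(wdays, min_periods=wdays)
            site_stat = roll.mean() if stat == "mean" else roll.sum()
            base_stat = broll.mean() if stat == "mean" else broll.sum()
            pieces[(var, wname)] = site_stat.sub(base_stat, axis=0)

    cols = {}
    sites = obs["site_id"].to_numpy()
    row_idx = full_range.get_indexer(obs_dates)
    for (var, wname), resid in pieces.items():
        prefix = "tmin" if var == "tmin_c" else "rain"
        col_map = {s: j for j, s in enumerate(resid.columns)}
        col_idx = np.array([col_map.get(s, -1) for s in sites])
        ok = (row_idx >= 0) & (col_idx >= 0)
        vals = np.full(len(obs), np.nan)
        mat = resid.to_numpy()
        vals[ok] = mat[row_idx[ok], col_idx[ok]]
        cols[f"{prefix}_{wname}_resid"] = vals

    out = pd.DataFrame(cols, index=obs.index)
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)][0]
        raise ValueError(
            f"insufficient weather history for observation {bad!r} "
            f"(site {obs.loc[bad, 'site_id']}, date {obs.loc[bad, 'date']}); "
            "need 90 days ending on the observation date"
        )
    return out


def solar_declination(day_of_year: int) -> float:
    """Solar declination (degrees): 23.44 sin(360 (284 + N) / 365)."""
    return 23.44 * math.sin(math.radians(360.0 * (284 + day_of_year) / 365.0))


def solar_position(latitude: float, day_of_year: int, hour: float):
    """Solar elevation and azimuth (degrees) at local solar time.

    Uses the standard geometry: hour angle H = 15 (hour - 12) degrees and
    sin h = sin(lat) sin(dec) + cos(lat) cos(dec) cos(H).  Azimuth is
    measured clockwise from north; before solar noon the sun is in the
    eastern half, after noon in the western half.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    phi = math.radians(latitude)
    dec = math.radians(solar_declination(day_of_year))
    H = math.radians(15.0 * (hour - 12.0))
    sin_h = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(H)
    sin_h = max(-1.0, min(1.0, sin_h))
    h = math.asin(sin_h)
    cos_h = math.cos(h)
    if cos_h < 1e-12:
        az = 180.0  # sun at the zenith: azimuth undefined, pick south
    else:
        cos_az = (math.sin(dec) - sin_h * math.sin(phi)) / (cos_h * math.cos(phi))
        cos_az = max(-1.0, min(1.0, cos_az))
        az = math.degrees(math.acos(cos_az))
        if H > 0:  # afternoon: west of the meridian
            az = 360.0 - az
    return math.degrees(h), az


def _beam_incidence(elevation_deg, azimuth_deg, slope_deg, aspect_deg):
    """cos of the beam's incidence angle onto a surface of given slope/aspect."""
    h = math.radians(elevation_deg)
    beta = math.radians(slope_deg)
    rel = math.radians(azimuth_deg - aspect_deg)
    return (math.cos(beta) * math.sin(h)
            + math.sin(beta) * math.cos(h) * math.cos(rel))


def solar_index(latitude: float, slope_deg: float, aspect_deg: float,
                year: int | None = None) -> float:
    """Mean direct-beam index over the year for a tilted site surface.

    At 12:00 solar time on the first day of each month the monthly index is
    ``max(0, cos theta_i)`` with ``theta_i`` the beam incidence angle to the
    surface normal, and 0 whenever the sun is below the horizon; the site
    value is the mean over the twelve months.  The geometry repeats on a
    non-leap calendar, so ``year`` does not alter the result; the parameter
    is kept because indices are reported per site-year.
    """
    total = 0.0
    for doy in _MONTH_START_DOY:
        elev, az = solar_position(latitude, doy, 12.0)
        if elev <= 0.0:
            continue
        total += max(0.0, _beam_incidence(elev, az, slope_deg, aspect_deg))
    return total / 12.0
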