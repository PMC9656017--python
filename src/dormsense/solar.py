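"""Solar geometry and clear-sky direct insolation.

Solar elevation/zenith angles are computed with the NOAA closed-form
algorithm (Meeus-class, accurate to well under 0.1 degrees for the decades
around J2000), which is ample for the flat-atmosphere air-mass model used
downstream.  Atmospheric refraction is deliberately ignored: the insolation
estimate is already a clear-sky idealization.

The direct component of insolation follows the classic air-mass
attenuation law

    I_D = 1.353 * 0.7 ** (AM ** 0.678),   AM = 1 / cos(theta),

with ``theta`` the solar zenith angle, ``AM`` the relative optical air
mass and ``I_D`` in kW m^-2.  1.353 kW m^-2 is the solar constant; 0.7 is
the fraction transmitted through one air mass.  Below the horizon
(theta >= 90 deg) the air mass is undefined and I_D is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SolarGeometry",
    "InsolationEstimate",
    "solar_position",
    "insolation",
    "SOLAR_CONSTANT_KW",
]

SOLAR_CONSTANT_KW = 1.353  # kW m^-2


@dataclass(frozen=True)
class SolarGeometry:
    """Sun position at one or more instants (angles in degrees)."""

    at: pd.DatetimeIndex
    latitude: float
    longitude: float
    elevation_angle: np.ndarray
    zenith_angle: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.zenith_angle < -1e-9) or np.any(self.zenith_angle > 180 + 1e-9):
            raise ValueError("zenith angle outside [0, 180] degrees")


@dataclass(frozen=True)
class InsolationEstimate:
    """Air mass and direct insolation (kW m^-2); AM is NaN below the horizon."""

    air_mass: np.ndarray
    direct_kw_m2: np.ndarray


def _to_utc_index(at) -> pd.DatetimeIndex:
    if isinstance(at, (str, pd.Timestamp)):
        at = pd.DatetimeIndex([pd.Timestamp(at)])
    elif not isinstance(at, pd.DatetimeIndex):
        at = pd.DatetimeIndex(at)
    if at.tz is None:
        raise ValueError(
            "naive timestamp is ambiguous: supply a timezone or UTC offset"
        )
    return at.tz_convert("UTC")


def solar_position(at, latitude: float, longitude: float) -> SolarGeometry:
    """Compute solar elevation and zenith angles (NOAA algorithm).

    Parameters
    ----------
    at : timestamp, sequence of timestamps or DatetimeIndex
        Timezone-aware instants; naive timestamps are rejected.
    latitude, longitude : float
        Site coordinates in degrees (east and north positive).

    Returns
    -------
    SolarGeometry
        Elevation and zenith angles in degrees, one per input instant.
    """
    idx = _to_utc_index(at)
    # Julian day from Unix epoch; NOAA formulas use the Julian century T
    jd = idx.asi8 / 1e9 / 86400.0 + 2440587.5
    t = (jd - 2451545.0) / 36525.0

    # Geometric mean longitude and anomaly of the sun (deg)
    l0 = np.mod(280.46646 + t * (36000.76983 + t * 0.0003032), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mrad = np.deg2rad(m)

    # Equation of center and true longitude
    c = (
        np.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))

    # Obliquity of the ecliptic, corrected for nutation
    seconds = 21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))
    e0 = 23.0 + (26.0 + seconds / 60.0) / 60.0
    eps = e0 + 0.00256 * np.cos(np.deg2rad(omega))
    eps_rad = np.deg2rad(eps)

    # Solar declination
    decl = np.arcsin(np.sin(eps_rad) * np.sin(np.deg2rad(app_long)))

    # Equation of time (minutes)
    y = np.tan(eps_rad / 2.0) ** 2
    l0rad = np.deg2rad(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * l0rad)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * y * np.sin(mrad) * np.cos(2 * l0rad)
        - 0.5 * y * y * np.sin(4 * l0rad)
        - 1.25 * ecc * ecc * np.sin(2 * mrad)
    )

    # True solar time -> hour angle (deg, negative before solar noon)
    minutes = (
        idx.hour * 60.0
        + idx.minute
        + idx.second / 60.0
        + idx.microsecond / 6e7
    )
    tst = np.mod(minutes + eqtime + 4.0 * longitude, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)

    lat_rad = np.deg2rad(latitude)
    cos_zen = np.sin(lat_rad) * np.sin(decl) + np.cos(lat_rad) * np.cos(decl) * np.cos(
        np.deg2rad(ha)
    )
    zenith = np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return SolarGeometry(
        at=idx,
        latitude=latitude,
        longitude=longitude,
        elevation_angle=90.0 - zenith,
        zenith_angle=zenith,
    )


def insolation(geometry) -> InsolationEstimate:
    """Clear-sky direct insolation from the air-mass attenuation law.

    Accepts a :class:`SolarGeometry` or a zenith angle (degrees, scalar or
    array).  For zenith >= 90 deg the sun is at or below the horizon:
    the air mass is reported as NaN and the direct insolation as 0.
    """
    if isinstance(geometry, SolarGeometry):
        zenith = geometry.zenith_angle
    else:
        zenith = np.asarray(geometry, dtype=float)
    zenith = np.atleast_1d(np.asarray(zenith, dtype=float))
    day = zenith < 90.0
    am = np.full(zenith.shape, np.nan)
    i_d = np.zeros(zenith.shape)
    am[day] = 1.0 / np.cos(np.deg2rad(zenith[day]))
    i_d[day] = SOLAR_CONSTANT_KW * 0.7 ** (am[day] ** 0.678)
    return InsolationEstimate(air_mass=am, direct_kw_m2=i_d)


def direct_insolation_series(index: pd.DatetimeIndex, latitude: float, longitude: float) -> pd.DataFrame:
    """Convenience: elevation, air mass and I_D for a timestamp grid."""
    geo = solar_position(index, latitude, longitude)
    est = insolation(geo)
    return pd.DataFrame(
        {
            "solar_elevation": geo.elevation_angle,
            "air_mass": est.air_mass,
            "insolation_direct": est.direct_kw_m2,
        },
        index=index,
    )
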