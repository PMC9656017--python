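import numpy as np
import pandas as pd
import pytest

from dormsense.synthetic import SeasonConfig, generate_season


@pytest.fixture(scope="session")
def default_season():
    """One seeded two-season dataset with ground truth, shared read-only."""
    return generate_season(SeasonConfig(seed=0))


@pytest.fixture(scope="session")
def short_config():
    """A single-winter config for cheaper end-to-end runs."""
    return SeasonConfig(start="2019-07-01T00:00:00Z", end="2020-07-01T00:00:00Z", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def psa_solar_elevation(ts_utc, lat, lon):
    """Independent solar-position oracle: PSA algorithm (Blanco-Muriel
    et al. 2001), sharing no code with the package's NOAA implementation."""
    ts = pd.Timestamp(ts_utc).tz_convert("UTC")
    jd = ts.value / 1e9 / 86400.0 + 2440587.5
    elapsed = jd - 2451545.0
    omega = 2.1429 - 0.0010394594 * elapsed
    mean_long = 4.8950630 + 0.017202791698 * elapsed
    anomaly = 6.2400600 + 0.0172019699 * elapsed
    ecl_long = (
        mean_long
        + 0.03341607 * np.sin(anomaly)
        + 0.00034894 * np.sin(2 * anomaly)
        - 0.0001134
        - 0.0000203 * np.sin(omega)
    )
    obliquity = 0.4090928 - 6.2140e-9 * elapsed + 0.0000396 * np.cos(omega)
    ra = np.arctan2(np.cos(obliquity) * np.sin(ecl_long), np.cos(ecl_long)) % (2 * np.pi)
    dec = np.arcsin(np.sin(obliquity) * np.sin(ecl_long))
    hour_ut = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    gmst = 6.6974243242 + 0.0657098283 * elapsed + hour_ut
    lmst = np.deg2rad(gmst * 15.0 + lon)
    hour_angle = lmst - ra
    lat_rad = np.deg2rad(lat)
    zen = np.arccos(
        np.cos(lat_rad) * np.cos(hour_angle) * np.cos(dec) + np.sin(dec) * np.sin(lat_rad)
    )
    zen += 6371.01 / 149597890.0 * np.sin(zen)  # parallax
    return 90.0 - np.rad2deg(zen)
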