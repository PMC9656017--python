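"""Alignment, outlier cleaning and regularization of the hourly dataset.

The measurement stream is anchored on the fluorometer timestamps: weather
records are linearly interpolated onto that grid (gaps longer than
``max_gap_hours`` stay masked), solar geometry and clear-sky insolation are
computed per timestamp, and JIP parameters are cleaned with the two-rule
filter: negative values, and values exceeding the parameter's normal range
more than tenfold, are set to zero and masked.  Spectral stages require a
strictly uniform gap-free grid, which :func:`regularize` provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .timefreq import LowpassConfig, lowpass

__all__ = [
    "AlignedDataset",
    "DEFAULT_NORMAL_RANGES",
    "align",
    "clean_outliers",
    "regularize",
]

#: Normal physiological ranges used by the tenfold-excess outlier rule.
#: 0.83-0.87 is the canonical healthy-plant ceiling for Fv/Fm; per-RC
#: energy fluxes rarely exceed a few units in viable tissue.
DEFAULT_NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "Fv_over_Fm": (0.0, 0.87),
    "VJ": (0.0, 1.0),
    "M0": (0.0, 20.0),
    "ABS_per_RC": (0.0, 20.0),
    "TR0_per_RC": (0.0, 20.0),
    "ET0_per_RC": (0.0, 20.0),
    "DI0_per_RC": (0.0, 20.0),
}

WEATHER_COLUMNS = (
    "air_T", "RH", "pressure", "precipitation", "wind_speed", "UV",
)
SOLAR_COLUMNS = ("solar_elevation", "insolation_direct")


@dataclass
class AlignedDataset:
    """Hourly-gridded table of JIP parameters, weather and solar columns.

    ``data`` holds the values (cleaned cells carry the exported zero);
    ``mask`` is True where a cell is valid.  Statistics must be computed on
    :meth:`valid`, never on raw ``data``, so zeroed outliers cannot leak.
    """

    data: pd.DataFrame
    mask: pd.DataFrame
    jip_columns: tuple[str, ...] = ()
    site: tuple[float, float] | None = None  # (latitude, longitude)

    def __post_init__(self):
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("AlignedDataset requires a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if self.mask is None:
            self.mask = self.data.notna()
        if not self.mask.index.equals(self.data.index) or list(self.mask.columns) != list(
            self.data.columns
        ):
            raise ValueError("mask must share the data grid")
        self.jip_columns = tuple(c for c in self.jip_columns if c in self.data.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def valid(self, column: str | None = None):
        """Data with invalid cells as NaN (whole frame or one column)."""
        if column is None:
            return self.data.where(self.mask)
        return self.data[column].where(self.mask[column])

    def copy(self) -> "AlignedDataset":
        return AlignedDataset(
            self.data.copy(), self.mask.copy(), self.jip_columns, self.site
        )

    def mask_counts(self) -> pd.Series:
        return (~self.mask).sum()


def _interp_with_gap_mask(
    target: pd.DatetimeIndex, source: pd.Series, max_gap_hours: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear time interpolation plus a validity mask.

    A target cell is invalid when it falls outside the source range
    (no extrapolation) or inside a source gap longer than max_gap_hours.
    """
    src = source.dropna()
    t_src = src.index.asi8 / 3.6e12  # hours
    t_tgt = target.asi8 / 3.6e12
    if len(src) < 2:
        return np.full(len(target), np.nan), np.zeros(len(target), bool)
    vals = np.interp(t_tgt, t_src, src.to_numpy(float))
    ok = (t_tgt >= t_src[0]) & (t_tgt <= t_src[-1])
    # gap rule: the bracketing source interval must be short enough
    right = np.searchsorted(t_src, t_tgt, side="left").clip(1, len(t_src) - 1)
    gap = t_src[right] - t_src[right - 1]
    ok &= gap <= max_gap_hours
    vals[~ok] = np.nan
    return vals, ok


def align(
    jip: pd.DataFrame,
    weather: pd.DataFrame,
    site: tuple[float, float],
    max_gap_hours: float = 6.0,
) -> AlignedDataset:
    """Interpolate weather onto the fluorometer timestamp grid.

    ``jip`` is indexed by measurement timestamp (tz-aware) with one column
    per JIP parameter; ``weather`` likewise with columns such as air_T.
    Solar elevation and direct insolation are computed per timestamp from
    the site coordinates.
    """
    if jip.empty or weather.empty:
        raise ValueError("both JIP and weather inputs must be non-empty")
    if jip.index.tz is None or weather.index.tz is None:
        raise ValueError("inputs must carry timezone-aware timestamps")
    jip = jip.sort_index()
    weather = weather.sort_index()
    lo = max(jip.index[0], weather.index[0])
    hi = min(jip.index[-1], weather.index[-1])
    if lo > hi:
        raise ValueError("JIP and weather time ranges do not overlap")

    grid = jip.index
    data = {c: jip[c].to_numpy(float) for c in jip.columns}
    mask = {c: np.isfinite(data[c]) for c in jip.columns}
    for col in weather.columns:
        vals, ok = _interp_with_gap_mask(grid, weather[col], max_gap_hours)
        data[col], mask[col] = vals, ok

    lat, lon = site
    sol = solar.direct_insolation_series(grid, lat, lon)
    for col in SOLAR_COLUMNS:
        data[col] = sol[col].to_numpy()
        mask[col] = np.ones(len(grid), bool)

    frame = pd.DataFrame(data, index=grid)
    return AlignedDataset(
        data=frame,
        mask=pd.DataFrame(mask, index=grid)[frame.columns],
        jip_columns=tuple(jip.columns),
        site=site,
    )


def clean_outliers(
    dataset: AlignedDataset,
    normal_ranges: dict[str, tuple[float, float]] | None = None,
) -> AlignedDataset:
    """Apply the two-rule cleanup to every JIP column.

    Negative values and values exceeding ten times the upper normal bound
    are set to zero (the value exported in raw-compatible CSVs) and masked
    out of all statistics.  Idempotent: a second pass changes nothing.
    """
    ranges = dict(DEFAULT_NORMAL_RANGES if normal_ranges is None else normal_ranges)
    out = dataset.copy()
    for col in dataset.jip_columns:
        if col not in ranges:
            raise KeyError(f"no normal range configured for JIP parameter {col!r}")
        _, upper = ranges[col]
        vals = out.data[col].to_numpy(float)
        bad = (vals < 0) | (vals > 10.0 * upper)
        vals[bad] = 0.0
        out.data[col] = vals
        out.mask[col] = out.mask[col] & ~bad
    return out


def regularize(
    dataset: AlignedDataset,
    fill_gap_hours: float = 24.0,
    max_missing_fraction: float = 0.5,
) -> AlignedDataset:
    """Snap to an exact hourly grid and fill every gap.

    Timestamps are rounded to the hour; short gaps (<= fill_gap_hours) are
    filled by linear time interpolation; longer gaps are filled with the
    column's lowpass trend and left flagged invalid in the mask.  Output is
    gap-free in ``data`` for all numeric columns.
    """
    df = dataset.valid()
    df.index = df.index.round("h")
    df = df[~df.index.duplicated(keep="first")]
    full = pd.date_range(df.index[0], df.index[-1], freq="h", tz=df.index.tz)
    df = df.reindex(full)

    data = {}
    mask = {}
    limit = max(1, int(round(fill_gap_hours)))
    for col in df.columns:
        s = df[col]
        frac_missing = s.isna().mean()
        if frac_missing > max_missing_fraction:
            raise ValueError(
                f"column {col!r} is {frac_missing:.0%} missing; cannot regularize"
            )
        short = s.interpolate(method="time", limit=limit, limit_area="inside")
        short = short.ffill(limit=limit).bfill(limit=limit)
        still = short.isna()
        if still.any():
            provisional = s.interpolate(method="time").ffill().bfill()
            trend = lowpass(provisional, LowpassConfig())
            short[still] = trend[still]
        data[col] = short
        mask[col] = s.notna()
    frame = pd.DataFrame(data, index=full)
    return AlignedDataset(
        data=frame,
        mask=pd.DataFrame(mask, index=full)[frame.columns],
        jip_columns=dataset.jip_columns,
        site=dataset.site,
    )
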