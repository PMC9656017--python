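"""Chilling-requirement accumulation models and release-date prediction.

Endo-dormancy in temperate fruit trees is released only after sufficient
exposure to chilling temperatures, conventionally accumulated hour by hour
as chill units (CU).  Four widespread stepwise models are provided, each a
piecewise-constant weight of hourly air temperature:

- ``chilling_hours`` (Weinberger 1950): 1 for each hour in the 0-7.2 C band;
- ``utah`` (Richardson et al. 1974): graded weights with negation above 16 C;
- ``low_chill`` (Gilreath & Buchanan 1981): Utah-like, shifted for mild climates;
- ``north_carolina`` (Shaltout & Unrath 1983): stronger negation at high T.

The weight tables ship as an editable CSV (``data/chill_weights.csv``).
Apple cultivars typically require 900-1500 CU depending on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CHILL_MODELS",
    "ChillingAccumulation",
    "chill_weights",
    "chill_accumulate",
    "predict_release",
]

CHILL_MODELS = ("chilling_hours", "utah", "low_chill", "north_carolina")


def chill_weights(model: str) -> pd.DataFrame:
    """Return the weight table (t_low_C, t_high_C, weight) for one model."""
    if model not in CHILL_MODELS:
        raise ValueError(f"unknown chill model {model!r}; choose from {CHILL_MODELS}")
    with resources.files("dormsense.data").joinpath("chill_weights.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    return table[table["model"] == model].reset_index(drop=True)


@dataclass
class ChillingAccumulation:
    """Hourly chill contributions and their running sum for one model."""

    model: str
    hourly_units: pd.Series
    cumulative: pd.Series
    start_of_accumulation: pd.Timestamp
    floored: bool = False

    def final(self) -> float:
        return float(self.cumulative.iloc[-1])


def _check_hourly(temperature: pd.Series) -> pd.Series:
    if not isinstance(temperature.index, pd.DatetimeIndex):
        raise TypeError("temperature series must have a DatetimeIndex")
    if temperature.isna().any():
        raise ValueError("temperature series contains missing values; fill gaps first")
    deltas = np.diff(temperature.index.asi8) / 3.6e12
    if len(deltas) and not np.allclose(deltas, 1.0, atol=1e-6):
        raise ValueError("temperature series is not hourly and gap-free")
    return temperature


def chill_accumulate(
    hourly_temperature: pd.Series,
    model: str = "utah",
    start: pd.Timestamp | str | None = None,
    floor_at_zero: bool = False,
) -> ChillingAccumulation:
    """Accumulate chill units from an hourly temperature series.

    Parameters
    ----------
    hourly_temperature : pandas.Series
        Air temperature in Celsius on a gap-free hourly DatetimeIndex.
    model : str
        One of :data:`CHILL_MODELS`.
    start : timestamp, optional
        Start of accumulation; earlier hours are dropped (default: first
        timestamp of the series).
    floor_at_zero : bool
        If True the running total is floored at zero, so warm spells before
        accumulation begins cannot drive it negative.  Published practice
        varies; both behaviours are exposed.
    """
    temperature = _check_hourly(hourly_temperature)
    if start is not None:
        temperature = temperature[temperature.index >= pd.Timestamp(start)]
    if temperature.empty:
        raise ValueError("no temperature data at or after the accumulation start")

    table = chill_weights(model)
    edges = np.concatenate([table["t_low_C"].to_numpy(), [np.inf]])
    weights = table["weight"].to_numpy()
    bins = np.searchsorted(edges, temperature.to_numpy(), side="right") - 1
    units = pd.Series(weights[bins], index=temperature.index, name=f"{model}_units")

    if floor_at_zero:
        total = np.empty(len(units))
        running = 0.0
        for i, u in enumerate(units.to_numpy()):
            running = max(0.0, running + u)
            total[i] = running
        cumulative = pd.Series(total, index=units.index, name=f"{model}_cumulative")
    else:
        cumulative = units.cumsum().rename(f"{model}_cumulative")
    return ChillingAccumulation(
        model=model,
        hourly_units=units,
        cumulative=cumulative,
        start_of_accumulation=temperature.index[0],
        floored=floor_at_zero,
    )


def predict_release(
    accumulation: ChillingAccumulation, requirement: float
) -> pd.Timestamp | None:
    """First timestamp at which the cumulative chill meets the requirement.

    Returns None when the requirement is never reached.  Apple chilling
    requirements typically fall between 900 and 1500 CU.
    """
    if requirement <= 0:
        raise ValueError("chilling requirement must be positive")
    met = accumulation.cumulative >= requirement
    if not met.any():
        return None
    return accumulation.cumulative.index[int(np.argmax(met.to_numpy()))]
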