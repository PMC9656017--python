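"""Statsmodels-style front end: fit the dormancy marker to a season record.

``DormancyModel`` takes one regular hourly JIP-parameter series (DI0/RC by
default — the thermal-dissipation flux whose weekly-band oscillation marks
eco-dormancy), and ``fit()`` runs the full spectral pipeline: lowpass
trend, Morlet spectrogram, weekly-band power, phase detection.  The
returned ``DormancyResults`` carries the timeline, per-season release
dates with a threshold-sensitivity uncertainty window, diagnostics and a
``summary()`` table; ``plot()`` draws the trend, the band power and the
detected phases.

Example
-------
>>> from dormsense.synthetic import SeasonConfig, generate_season
>>> from dormsense.model import DormancyModel
>>> dataset, truth = generate_season(SeasonConfig(seed=1))
>>> res = DormancyModel.from_dataset(dataset).fit()
>>> len(res.release_dates)
2
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocessing import AlignedDataset, regularize
from .timefreq import (
    DetectionConfig,
    DormancyTimeline,
    LowpassConfig,
    Spectrogram,
    SpectrogramConfig,
    band_power,
    cwt_spectrogram,
    detect_dormancy,
    lowpass,
)

__all__ = ["DormancyModel", "DormancyResults"]


class DormancyModel:
    """Dormancy-phase model for one JIP-parameter time series.

    Parameters
    ----------
    series : pandas.Series
        Gap-free hourly series of the marker parameter (tz-aware index).
    lowpass_config, spectrogram_config, detection_config :
        Stage configurations; defaults follow the standard analysis
        ((one week)^-1 cutoff, Morlet w0=6 over 1-512 h, quantile +
        prominence detection rule).
    band_center_h, bandwidth_octaves :
        The spectral band used as the dormancy marker (one octave around
        168 h by default).
    """

    def __init__(
        self,
        series: pd.Series,
        lowpass_config: LowpassConfig = LowpassConfig(),
        spectrogram_config: SpectrogramConfig = SpectrogramConfig(),
        detection_config: DetectionConfig = DetectionConfig(),
        band_center_h: float = 168.0,
        bandwidth_octaves: float = 1.0,
    ):
        if series.isna().any():
            raise ValueError("series has gaps; regularize the dataset first")
        self.series = series
        self.lowpass_config = lowpass_config
        self.spectrogram_config = spectrogram_config
        self.detection_config = replace(detection_config, band_center_h=band_center_h)
        self.band_center_h = band_center_h
        self.bandwidth_octaves = bandwidth_octaves

    @classmethod
    def from_dataset(
        cls, dataset: AlignedDataset, parameter: str = "DI0_per_RC", **kwargs
    ) -> "DormancyModel":
        """Build from an aligned dataset, filling any gaps first."""
        s = dataset.valid(parameter)
        if s.isna().any():
            s = regularize(dataset).data[parameter]
        return cls(s.rename(parameter), **kwargs)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, parameter: str = "DI0_per_RC", **kwargs
    ) -> "DormancyModel":
        return cls(data[parameter].rename(parameter), **kwargs)

    def fit(self) -> "DormancyResults":
        trend = lowpass(self.series, self.lowpass_config)
        spec = cwt_spectrogram(self.series, self.spectrogram_config)
        power = band_power(spec, self.band_center_h, self.bandwidth_octaves)
        timeline = detect_dormancy(power, trend, self.detection_config)
        windows = self._release_windows(power, trend)
        return DormancyResults(
            model=self,
            trend=trend,
            spectrogram=spec,
            band_power=power,
            timeline=timeline,
            release_windows=windows,
        )

    def _release_windows(self, power: pd.Series, trend: pd.Series) -> list:
        """Sensitivity of each release date to the detection quantile.

        The detection threshold is the main judgement call, so the
        uncertainty window spans the release dates obtained at quantiles
        +-0.05 around the configured one, matched per season.
        """
        q = self.detection_config.power_quantile
        dates = {}
        for dq in (-0.05, 0.0, 0.05):
            cfg = replace(self.detection_config, power_quantile=min(0.99, max(0.01, q + dq)))
            tl = detect_dormancy(power, trend, cfg)
            dates[dq] = tl.release_dates
        central = dates[0.0]
        windows = []
        for r in central:
            near = [
                min(alt, key=lambda d: abs(d - r))
                for alt in (dates[-0.05], dates[0.05])
                if alt
            ]
            lo = min([r, *near])
            hi = max([r, *near])
            windows.append((lo, hi))
        return windows


@dataclass
class DormancyResults:
    """Fitted dormancy timeline and its diagnostics."""

    model: DormancyModel
    trend: pd.Series
    spectrogram: Spectrogram
    band_power: pd.Series
    timeline: DormancyTimeline
    release_windows: list

    @property
    def release_dates(self) -> list:
        return self.timeline.release_dates

    @property
    def threshold(self) -> float:
        return self.timeline.threshold

    def phase_at(self, when) -> str:
        """Phase label at an instant (intervals are half-open on the right,
        so a release date answers 'eco')."""
        ts = pd.Timestamp(when)
        last = self.timeline.intervals[-1] if self.timeline.intervals else None
        for iv in self.timeline.intervals:
            if iv.start <= ts < iv.end or (iv is last and ts == iv.end):
                return iv.phase
        return "unknown"

    def score_against(self, truth) -> pd.DataFrame:
        """Release-date errors (days) against generator ground truth."""
        rows = []
        for r in self.release_dates:
            true = min(truth.release_dates, key=lambda d: abs(d - r))
            rows.append(
                {
                    "detected": r,
                    "truth": true,
                    "error_days": (r - true) / pd.Timedelta(days=1),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Dormancy marker analysis",
            "=" * 60,
            f"parameter:            {self.model.series.name}",
            f"observations:         {len(self.model.series)} hourly",
            f"record:               {self.model.series.index[0]} .. {self.model.series.index[-1]}",
            f"band:                 {self.model.band_center_h:g} h "
            f"(+-{self.model.bandwidth_octaves / 2:g} octave)",
            f"power threshold:      {self.threshold:.4g} "
            f"(q={self.model.detection_config.power_quantile:g} of record)",
            f"eco intervals:        {len(self.timeline.eco_intervals())}",
        ]
        for iv, (lo, hi) in zip(self.timeline.eco_intervals(), self.release_windows):
            lines.append(
                f"  release {iv.start.date()}  window [{lo.date()} .. {hi.date()}]"
                f"  mean weekly power {iv.mean_band_power:.3g}"
            )
        lines.append("phases: " + ", ".join(
            f"{iv.phase} {iv.start.date()}..{iv.end.date()}" for iv in self.timeline.intervals
        ))
        return "\n".join(lines)

    def plot(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 1, sharex=True, figsize=(11, 6))
        ax0, ax1 = axes
        ax0.plot(self.model.series.index, self.model.series, lw=0.3, alpha=0.5)
        ax0.plot(self.trend.index, self.trend, lw=1.5)
        ax0.set_ylabel(str(self.model.series.name))
        ax1.plot(self.band_power.index, self.band_power, lw=0.8)
        ax1.axhline(self.threshold, color="k", ls="--", lw=0.8)
        ax1.set_ylabel("weekly-band power")
        shade = {"endo": "#c6dbef", "eco": "#fdd0a2"}
        for iv in self.timeline.intervals:
            if iv.phase in shade:
                for ax in (ax0, ax1):
                    ax.axvspan(iv.start, iv.end, color=shade[iv.phase], alpha=0.5)
        return axes
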