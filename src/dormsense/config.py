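"""Pipeline configuration: YAML-backed, validated, unknown keys rejected.

Timestamps are exchanged in ISO-8601 with explicit UTC offsets and all
internal computation happens in UTC, so local-time ambiguity never enters
the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .preprocessing import DEFAULT_NORMAL_RANGES

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SiteSettings(_Strict):
    latitude: float = 55.7078
    longitude: float = 37.5268


class SimulateSettings(_Strict):
    start: str = "2019-07-01T00:00:00Z"
    end: str = "2021-07-01T00:00:00Z"
    weekly_mod_amplitude: float = 0.25
    gap_fraction: float = 0.0
    n_example_transients: int = 24


class JipSettings(_Strict):
    segment_end_us: float = 300.0


class PreprocessSettings(_Strict):
    max_gap_hours: float = 6.0
    fill_gap_hours: float = 24.0
    normal_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_NORMAL_RANGES)
    )


class LowpassSettings(_Strict):
    cutoff_period_h: float = 168.0
    transition_width_h: float = 168.0


class SpectrogramSettings(_Strict):
    w0: float = 6.0
    period_min_h: float = 1.0
    period_max_h: float = 512.0
    voices_per_octave: int = 8


class DetectionSettings(_Strict):
    parameter: str = "DI0_per_RC"
    band_center_h: float = 168.0
    bandwidth_octaves: float = 1.0
    power_quantile: float = 0.75
    min_duration_days: float = 14.0
    merge_gap_days: float = 7.0
    min_contrast: float = 10.0


class ChillSettings(_Strict):
    model: str = "utah"
    requirement: float = 1200.0
    start_month: int = 9
    start_day: int = 1
    floor_at_zero: bool = False


class PipelineConfig(_Strict):
    """Every stage's knobs, each with a documented default."""

    site: SiteSettings = Field(default_factory=SiteSettings)
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    jip: JipSettings = Field(default_factory=JipSettings)
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    lowpass: LowpassSettings = Field(default_factory=LowpassSettings)
    spectrogram: SpectrogramSettings = Field(default_factory=SpectrogramSettings)
    detection: DetectionSettings = Field(default_factory=DetectionSettings)
    chill: ChillSettings = Field(default_factory=ChillSettings)
    seed: int = 0
    out_dir: str = "dormsense_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def load_config(path=None, **overrides) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    return cfg.model_copy(update=overrides) if overrides else cfg
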