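"""End-to-end pipeline: simulate -> jip -> preprocess -> stats -> analyze
-> chill -> detect, every stage writing a versioned CSV.

All randomness flows from the single config seed; with fixed inputs and
seed the outputs are byte-identical run to run.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chilling, stats, transients
from .config import PipelineConfig
from .model import DormancyModel
from .preprocessing import clean_outliers, regularize
from .synthetic import SeasonConfig, generate_labelled_transients, generate_season
from .timefreq import DetectionConfig, LowpassConfig, SpectrogramConfig

log = logging.getLogger("dormsense")

__all__ = ["run_pipeline", "season_config_from", "write_csv"]

SCHEMA_VERSION = 1


def write_csv(df: pd.DataFrame, path: Path, name: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dormsense {name} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index)


def season_config_from(config: PipelineConfig) -> SeasonConfig:
    return SeasonConfig(
        start=config.simulate.start,
        end=config.simulate.end,
        latitude=config.site.latitude,
        longitude=config.site.longitude,
        weekly_mod_amplitude=config.simulate.weekly_mod_amplitude,
        gap_fraction=config.simulate.gap_fraction,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated record and write the outputs.

    Returns a dict of the in-memory artifacts keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # simulate
    season_cfg = season_config_from(config)
    dataset, truth = generate_season(season_cfg)
    log.info("simulate: %d hourly rows", len(dataset.timestamps))
    write_csv(dataset.data, out / "aligned_raw.csv", "aligned dataset")
    write_csv(truth.phase.to_frame(), out / "ground_truth.csv", "ground truth phases")
    artifacts["dataset"], artifacts["truth"] = dataset, truth

    # jip on a handful of example transients (the season series itself is
    # generated at the parameter level)
    pairs = generate_labelled_transients(
        n_per_class=max(1, config.simulate.n_example_transients // 2),
        noise_sd=0.02,
        seed=config.seed + 1,
    )
    params = [
        transients.compute_jip(t, config.jip.segment_end_us) for t, _ in pairs
    ]
    verdicts = [
        transients.classify_frost_damage(p, t).status
        for p, (t, _) in zip(params, pairs)
    ]
    jip_df = transients.jip_frame(params)
    jip_df["frost_verdict"] = verdicts
    jip_df["true_label"] = [lbl for _, lbl in pairs]
    write_csv(jip_df, out / "jip_parameters.csv", "jip parameters", index=False)
    artifacts["jip"] = jip_df

    # preprocess
    cleaned = clean_outliers(dataset, config.preprocess.normal_ranges)
    regular = regularize(cleaned, config.preprocess.fill_gap_hours)
    log.info("preprocess: %s masked cells", int(cleaned.mask_counts().sum()))
    write_csv(regular.data, out / "aligned_clean.csv", "cleaned regular dataset")
    artifacts["regular"] = regular

    # stats
    corr = stats.correlation_matrix(regular, columns=list(regular.jip_columns) + ["air_T", "UV", "insolation_direct"])
    write_csv(corr.to_long(), out / "correlations.csv", "correlation matrix", index=False)
    fits = pd.DataFrame(
        [stats.fit_volatility(regular, p).to_dict() for p in regular.jip_columns]
    )
    write_csv(fits, out / "volatility_fits.csv", "volatility fits", index=False)
    artifacts["correlations"], artifacts["fits"] = corr, fits

    # analyze + detect
    model = DormancyModel.from_dataset(
        regular,
        config.detection.parameter,
        lowpass_config=LowpassConfig(
            config.lowpass.cutoff_period_h, config.lowpass.transition_width_h
        ),
        spectrogram_config=SpectrogramConfig(
            config.spectrogram.w0,
            config.spectrogram.period_min_h,
            config.spectrogram.period_max_h,
            config.spectrogram.voices_per_octave,
        ),
        detection_config=DetectionConfig(
            power_quantile=config.detection.power_quantile,
            min_duration_days=config.detection.min_duration_days,
            merge_gap_days=config.detection.merge_gap_days,
            min_contrast=config.detection.min_contrast,
            w0=config.spectrogram.w0,
        ),
        band_center_h=config.detection.band_center_h,
        bandwidth_octaves=config.detection.bandwidth_octaves,
    )
    results = model.fit()
    write_csv(
        results.spectrogram.to_frame(), out / "spectrogram.csv", "spectrogram", index=False
    )
    write_csv(results.timeline.to_frame(), out / "timeline.csv", "dormancy timeline", index=False)
    log.info(
        "detect: %d eco intervals, releases %s",
        len(results.timeline.eco_intervals()),
        [str(d.date()) for d in results.release_dates],
    )
    artifacts["results"] = results

    # chill
    temp = regular.data["air_T"]
    years = sorted({ts.year for ts in temp.index})
    chill_rows = []
    for year in years:
        start = pd.Timestamp(
            year=year, month=config.chill.start_month, day=config.chill.start_day,
            tz=temp.index.tz,
        )
        if start < temp.index[0] or start >= temp.index[-1]:
            continue
        season_T = temp[temp.index >= start]
        acc = chilling.chill_accumulate(
            season_T, config.chill.model, start, config.chill.floor_at_zero
        )
        release = chilling.predict_release(acc, config.chill.requirement)
        chill_rows.append(
            {
                "season_start": start,
                "model": config.chill.model,
                "requirement": config.chill.requirement,
                "predicted_release": release,
                "final_cumulative": acc.final(),
            }
        )
    chill_df = pd.DataFrame(chill_rows)
    write_csv(chill_df, out / "chill.csv", "chilling predictions", index=False)
    artifacts["chill"] = chill_df
    return artifacts
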