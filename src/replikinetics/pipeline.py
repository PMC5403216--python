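"""End-to-end orchestration of the tracking, dwell-time and FRAP stages.

A :class:`RunConfig` (YAML or dict) carries the acquisition settings, all
filter thresholds (with the standard defaults) and bootstrap settings.
``run_dwell_pipeline`` composes: link -> optional fragment re-linkage ->
immobile PSF filter -> min-localization threshold -> intensity mixture ->
truncated-exponential MLE -> bleach correction -> bootstrap -> model
selection.  ``run_frap_pipeline`` composes: filter -> normalize ->
baseline correction -> collation -> recovery fit -> bootstrap.  Reports
embed the config hash, seed and package version so identical inputs yield
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import dwell, frap, tracking
from .acquisition import AcquisitionSettings
from .errors import ConfigurationError, InputError

log = logging.getLogger("replikinetics")


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run (versioned schema)."""

    schema_version: int = 1
    mode: str = "dwell"  # simulate | track | dwell | frap | metrics | end-to-end
    localization_csvs: list[str] = dataclasses.field(default_factory=list)
    control_csv: str | None = None  # bleach-control localization table
    control_durations_csv: str | None = None  # or precomputed durations
    frap_traces_csv: str | None = None
    output_dir: str = "results"
    exposure_time: float = 0.5
    interval_time: float = 1.0
    n_frames: int = 600
    control_exposure_time: float = 0.5
    control_interval_time: float = 0.5
    link_radius: float = tracking.DEFAULT_LINK_RADIUS
    link_memory: int = tracking.DEFAULT_MEMORY
    fragment_link: bool = False
    fragment_max_gap: int = tracking.DEFAULT_FRAGMENT_GAP
    psf_threshold_x: float = tracking.DEFAULT_PSF_THRESHOLD_X
    psf_threshold_y: float = tracking.DEFAULT_PSF_THRESHOLD_Y
    min_localizations: int | None = None
    gmm_components: int | None = 2  # 3 for out-of-focus spikes; None -> BIC-selected
    n_boot: int = 10_000
    bootstrap_method: str = "BCa"
    frame_correction: bool = True
    constrained: bool = False
    two_exponential_test: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def settings(self) -> AcquisitionSettings:
        return AcquisitionSettings(self.exposure_time, self.interval_time, self.n_frames)

    @property
    def control_settings(self) -> AcquisitionSettings:
        return AcquisitionSettings(
            self.control_exposure_time, self.control_interval_time, self.n_frames)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _report_header(config: RunConfig) -> dict:
    return {
        "package_version": _version,
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }


def _write_report(report: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _durations_from_table(
    table: pd.DataFrame, config: RunConfig, settings: AcquisitionSettings,
    stage_log: list[dict], label: str,
) -> dwell.TrackDurationSample:
    tracks = tracking.link_localizations(table, config.link_radius, config.link_memory)
    stage_log.append({"stage": f"{label}:link", "n_tracks": len(tracks)})
    if config.fragment_link:
        tracks = tracking.link_track_fragments(
            tracks, config.fragment_max_gap, config.link_radius)
        stage_log.append({"stage": f"{label}:fragment-link", "n_tracks": len(tracks)})
    tracks = tracking.filter_immobile(
        tracks, config.psf_threshold_x, config.psf_threshold_y)
    stage_log.append({"stage": f"{label}:immobile-filter", "n_tracks": len(tracks)})
    tracks, trunc = tracking.apply_min_localization_threshold(
        tracks, settings.interval_time, config.min_localizations)
    stage_log.append({"stage": f"{label}:min-localizations", "n_tracks": len(tracks),
                      "truncation_point_s": trunc})
    if len(tracks) >= 10:
        _, tracks = tracking.fit_intensity_gmm(tracks, config.gmm_components)
        stage_log.append({"stage": f"{label}:intensity-gmm",
                          "n_single_molecule_tracks": len(tracks)})
    else:
        stage_log.append({"stage": f"{label}:intensity-gmm", "skipped": "fewer than 10 tracks"})
    if not tracks:
        raise InputError(f"no tracks left after filtering for {label}")
    return tracking.tracks_to_duration_sample(tracks, settings, trunc, label=label)


def run_dwell_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Full sptPALM bound-time pipeline from localization tables to a report."""
    if not config.localization_csvs:
        raise InputError("no localization tables configured")
    stage_log: list[dict] = []

    all_durations = []
    trunc = None
    for path in config.localization_csvs:
        table = tracking.read_localization_table(path)
        if table.empty:
            raise InputError(f"empty localization table: {path}")
        sample = _durations_from_table(table, config, config.settings,
                                       stage_log, Path(path).stem)
        all_durations.append(sample.durations)
        trunc = sample.truncation_point
    amalgamated = dwell.TrackDurationSample(
        durations=np.concatenate(all_durations), truncation_point=trunc,
        settings=config.settings, label="amalgamated")
    stage_log.append({"stage": "amalgamate", "n_durations": amalgamated.n})

    if config.control_durations_csv:
        ctrl_df = pd.read_csv(config.control_durations_csv)
        if "duration_s" not in ctrl_df.columns:
            raise InputError("control durations CSV needs a duration_s column")
        c_settings = config.control_settings
        c_min = tracking.apply_min_localization_threshold(
            [], c_settings.interval_time, config.min_localizations)[1]
        control = dwell.TrackDurationSample(
            durations=ctrl_df["duration_s"].to_numpy(dtype=float),
            truncation_point=c_min, settings=c_settings, label="control")
    elif config.control_csv:
        table = tracking.read_localization_table(config.control_csv)
        control = _durations_from_table(table, config, config.control_settings,
                                        stage_log, "control")
    else:
        raise InputError("a bleach-control input is required")
    calibration = dwell.calibrate_bleach(control, config.frame_correction)
    stage_log.append({"stage": "bleach-calibration",
                      "t_constant_s": calibration.t_constant,
                      "n_control": control.n})

    if config.constrained:
        estimate = dwell.constrained_fit(
            amalgamated, calibration,
            frame_correction=config.frame_correction,
            n_boot=min(config.n_boot, 2000), seed=config.seed)
    else:
        estimate = dwell.bootstrap_estimate(
            amalgamated, calibration, n_boot=config.n_boot,
            method=config.bootstrap_method, seed=config.seed,
            frame_correction=config.frame_correction)

    report = _report_header(config)
    report["stages"] = stage_log
    report["estimate"] = estimate.to_dict()

    if config.two_exponential_test and amalgamated.n >= 10:
        single = dwell.fit_truncated_exponential(amalgamated)
        two = dwell.fit_two_exponential(amalgamated, calibration)
        decision = dwell.select_model(single, two)
        report["model_selection"] = {
            "choice": decision.choice,
            "bic_single": decision.bic_single,
            "bic_two": decision.bic_two,
            "llr_p_value": decision.llr_p_value,
            "reasons": decision.reasons,
            "two_exp": {"p": two.p, "tau1": two.tau1, "tau2": two.tau2},
        }

    if write:
        outdir = Path(config.output_dir)
        _write_report(report, outdir / "dwell_report.json")
        pd.DataFrame({"duration_s": amalgamated.durations}).to_csv(
            outdir / "durations.csv", index=False)
    for entry in stage_log:
        log.info("%s", entry)
    return report


def run_frap_pipeline(config: RunConfig, write: bool = True) -> dict:
    """FRAP pipeline from a trace CSV to a recovery-fit report."""
    if not config.frap_traces_csv:
        raise InputError("no FRAP trace CSV configured")
    df = pd.read_csv(config.frap_traces_csv)
    if df.empty:
        raise InputError("empty FRAP trace table")
    traces = frap.frame_to_traces(df)
    stage_log = [{"stage": "load", "n_traces": len(traces)}]

    focus = [t for t in traces if t.roi_type == "focus"]
    cells = [t for t in traces if t.roi_type == "cell"]
    controls = [t for t in traces if t.roi_type == "control_focus"]

    focus = frap.filter_traces(focus)
    stage_log.append({"stage": "filter", "n_traces": len(focus)})
    if not focus:
        raise InputError("no focus traces survive filtering")
    focus = [frap.normalize_trace(t) for t in focus]

    if controls:
        baseline = frap.fit_bleach_baseline(controls)
        focus = [frap.correct_photobleach(t, baseline) for t in focus]
        stage_log.append({"stage": "bleach-baseline", "rate_per_s": baseline.rate})
    max_recovery = frap.estimate_max_recovery(cells) if cells else 1.0
    stage_log.append({"stage": "max-recovery", "value": max_recovery})

    mean_trace = frap.average_and_collate(focus)
    fit = frap.fit_recovery(mean_trace, max_recovery, traces=focus,
                            n_boot=config.n_boot, seed=config.seed)
    stage_log.append({"stage": "fit", "status": fit.status})

    report = _report_header(config)
    report["stages"] = stage_log
    report["fit"] = fit.to_dict()
    if write:
        outdir = Path(config.output_dir)
        _write_report(report, outdir / "frap_report.json")
        frap.traces_to_frame([mean_trace]).to_csv(
            outdir / "mean_trace.csv", index=False)
    for entry in stage_log:
        log.info("%s", entry)
    return report
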