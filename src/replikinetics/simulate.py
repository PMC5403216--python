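"""Synthetic single-molecule data with known ground truth.

Generates the three kinds of input the inference pipeline consumes:

* **track-duration samples** — per-molecule focus lifetimes under a given
  exposure/interval protocol.  Binding times are exponential with mean
  ``true_bound_time``; photobleaching is exponential in *accumulated
  exposure* with constant-exposure mean ``constant_exposure_bleach_time``,
  so stroboscopic protocols stretch the effective bleach time by
  ``interval/exposure`` by construction.  Durations are quantized to whole
  frames times the interval, and tracks shorter than the configured
  minimum-localization threshold are dropped (recorded as the truncation
  point).
* **localization tables** — per-frame spot lists mixing immobile bound
  molecules (sharp PSFs, fixed positions plus localization noise, blinking
  gaps) with diffusing molecules (wide PSFs, scattered positions) and
  single- vs multi-molecule intensity populations.
* **FRAP traces** — reaction-limited recovery ``c - a exp(-b t)`` under a
  global exponential photobleaching decay, with Gaussian camera noise, plus
  whole-cell and unbleached-control ROIs.

Every generator draws all randomness from one explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSettings, scaled_bleach_time
from .dwell import TrackDurationSample
from .errors import InvalidParameterError
from .frap import FrapTrace
from .tracking import LOCALIZATION_COLUMNS, MIN_LOCALIZATIONS

# mMaple-class blink statistics: about half the molecules blink, averaging
# a few dark events apiece with sub-second dark times
DEFAULT_BLINK_PROBABILITY = 0.49
DEFAULT_MEAN_BLINK_EVENTS = 3.4
DEFAULT_BLINK_TIME_CONSTANT = 0.4  # s
DEFAULT_T_CONSTANT = 15.0  # s of accumulated exposure to bleach


@dataclass
class TrackSimParams:
    """Ground-truth kinetic and photophysical parameters for one simulation."""

    true_bound_time: float  # s, 1/k_off; may be inf for a stable binder
    constant_exposure_bleach_time: float = DEFAULT_T_CONSTANT
    blink_probability: float = DEFAULT_BLINK_PROBABILITY
    blink_time_constant: float = DEFAULT_BLINK_TIME_CONSTANT
    mean_blink_events: float = DEFAULT_MEAN_BLINK_EVENTS
    n_molecules: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_bound_time > 0:
            raise InvalidParameterError("true_bound_time must be positive")
        if not self.constant_exposure_bleach_time > 0:
            raise InvalidParameterError("constant_exposure_bleach_time must be positive")
        if not self.blink_time_constant > 0:
            raise InvalidParameterError("blink_time_constant must be positive")
        if not 0 <= self.blink_probability <= 1:
            raise InvalidParameterError("blink_probability must be in [0, 1]")
        if self.n_molecules < 1:
            raise InvalidParameterError("n_molecules must be >= 1")


@dataclass
class MixtureSpec:
    """PSF-width and intensity mixtures for localization-table synthesis.

    PSF widths (nm) are Gaussian per population; intensities (camera counts)
    are Gaussian per brightness class.  ``diffusing_fraction`` is the
    fraction of all molecules that are diffusing rather than bound;
    ``multi_fraction`` the fraction of bound molecules that are unresolved
    multi-molecule foci (double brightness).
    """

    bound_sigma: tuple[float, float] = (100.0, 15.0)
    diffusing_sigma: tuple[float, float] = (200.0, 30.0)
    single_intensity: tuple[float, float] = (1000.0, 150.0)
    multi_intensity: tuple[float, float] = (2000.0, 220.0)
    background: tuple[float, float] = (100.0, 10.0)
    diffusing_fraction: float = 0.5
    multi_fraction: float = 0.15
    localization_noise_sd: float = 20.0  # nm, per axis
    diffusing_step_sd: float = 400.0  # nm per frame, breaks 300 nm linking
    fov_size: float = 20000.0  # nm

    def __post_init__(self) -> None:
        for name in ("bound_sigma", "diffusing_sigma", "single_intensity",
                     "multi_intensity", "background"):
            mu, sd = getattr(self, name)
            if mu <= 0 or sd < 0:
                raise InvalidParameterError(f"invalid {name}: ({mu}, {sd})")
        if not 0 <= self.diffusing_fraction < 1:
            raise InvalidParameterError("diffusing_fraction must be in [0, 1)")
        if not 0 <= self.multi_fraction <= 1:
            raise InvalidParameterError("multi_fraction must be in [0, 1]")
        if self.localization_noise_sd < 0:
            raise InvalidParameterError("localization_noise_sd must be >= 0")


@dataclass
class FrapSimParams:
    """Ground truth for FRAP trace synthesis (recovery ``c - a exp(-b t)``)."""

    asymptote: float = 0.8  # c
    amplitude: float = 0.5  # a
    unbinding_rate: float = 0.25  # b, per second
    global_bleach_time: float = 300.0  # s; inf disables acquisition bleaching
    noise_sd: float = 0.02
    n_prebleach: int = 2
    sample_times: np.ndarray | None = None
    seed: int = 0
    n_traces: int = 48
    n_control: int = 20
    cell_residual_fraction: float = 0.9  # cell intensity left right after the pulse
    cell_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= self.asymptote <= 1.1:
            raise InvalidParameterError("need 0 < amplitude <= asymptote <= 1.1")
        if not self.unbinding_rate > 0:
            raise InvalidParameterError("unbinding_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_prebleach < 2:
            raise InvalidParameterError("need at least two pre-bleach points")
        if self.sample_times is None:
            pre = -2.0 * np.arange(self.n_prebleach, 0, -1)
            post = np.arange(0.0, 41.0, 1.0)
            self.sample_times = np.concatenate([pre, post])
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(self.sample_times) <= 0):
            raise InvalidParameterError("sample_times must be strictly increasing")
        if np.any(self.sample_times[: self.n_prebleach] >= 0):
            raise InvalidParameterError("first n_prebleach sample_times must be < 0")
        if abs(self.sample_times[self.n_prebleach]) > 1e-9:
            raise InvalidParameterError("the first post-bleach sample time must be 0")


@dataclass
class FrapTraceSet:
    """Simulated FRAP dataset: focus, whole-cell and control-focus ROIs."""

    traces: list[FrapTrace]
    ground_truth: dict

    def by_roi(self, roi_type: str) -> list[FrapTrace]:
        return [tr for tr in self.traces if tr.roi_type == roi_type]


# ---------------------------------------------------------------------------
# track durations
# ---------------------------------------------------------------------------


def _min_localizations(settings: AcquisitionSettings,
                       override: int | None) -> int:
    if override is not None:
        return override
    for key, val in MIN_LOCALIZATIONS.items():
        if math.isclose(settings.interval_time, key, rel_tol=1e-6):
            return val
    return 2  # conservative fallback for unconfigured intervals


def _frame_counts(params: TrackSimParams, settings: AcquisitionSettings,
                  rng: np.random.Generator) -> np.ndarray:
    """Number of frames each molecule appears, before any threshold.

    The per-frame survival probability is
    ``exp(-interval/T_bound) * exp(-exposure/T_constant)``, i.e. the track
    ends at combined rate ``1/T_bound + 1/T_bleach`` with
    ``T_bleach = (interval/exposure) * T_constant``.
    """
    n = params.n_molecules
    if math.isinf(params.true_bound_time):
        t_bind = np.full(n, np.inf)
    else:
        t_bind = rng.exponential(params.true_bound_time, n)
    x_bleach = rng.exponential(params.constant_exposure_bleach_time, n)
    k_bind = np.ceil(t_bind / settings.interval_time)
    k_bleach = np.ceil(x_bleach / settings.exposure_time)
    k = np.minimum(k_bind, k_bleach)
    return np.maximum(k, 1.0)


def gen_track_durations(
    params: TrackSimParams,
    settings: AcquisitionSettings,
    min_localizations: int | None = None,
) -> TrackDurationSample:
    """Simulate frame-quantized track durations with known ground truth.

    Returns only tracks meeting the minimum-localization threshold; the
    sample records the implied truncation point
    ``min_localizations * interval``.
    """
    rng = np.random.default_rng(params.seed)
    k = _frame_counts(params, settings, rng)
    min_loc = _min_localizations(settings, min_localizations)
    k = k[k >= min_loc]
    durations = k * settings.interval_time
    t_bleach = scaled_bleach_time(params.constant_exposure_bleach_time, settings)
    k_off = 0.0 if math.isinf(params.true_bound_time) else 1.0 / params.true_bound_time
    truth = {
        "true_bound_time": params.true_bound_time,
        "t_constant": params.constant_exposure_bleach_time,
        "t_bleach": t_bleach,
        "k_track": k_off + 1.0 / t_bleach,
        "n_generated": params.n_molecules,
        "seed": params.seed,
    }
    return TrackDurationSample(
        durations=durations,
        truncation_point=min_loc * settings.interval_time,
        settings=settings,
        label="simulated",
        ground_truth=truth,
    )


def gen_bleach_control(
    params: TrackSimParams,
    settings: AcquisitionSettings,
    min_localizations: int | None = None,
) -> TrackDurationSample:
    """Stable-binder control: identical to track simulation with k_off = 0.

    Emulates a LacI-operator-array strain whose unbinding is negligible, so
    focus disappearance is governed by photobleaching alone.
    """
    stable = TrackSimParams(
        true_bound_time=math.inf,
        constant_exposure_bleach_time=params.constant_exposure_bleach_time,
        blink_probability=params.blink_probability,
        blink_time_constant=params.blink_time_constant,
        mean_blink_events=params.mean_blink_events,
        n_molecules=params.n_molecules,
        seed=params.seed,
    )
    sample = gen_track_durations(stable, settings, min_localizations)
    sample.label = "bleach-control"
    return sample


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------


def gen_localization_table(
    params: TrackSimParams,
    settings: AcquisitionSettings,
    mixture: MixtureSpec,
    max_blink_gap_frames: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Synthesize a per-frame localization table plus ground-truth bookkeeping.

    Bound molecules appear as runs of localizations at a fixed position
    (plus localization noise) with optional blinking gaps; diffusing
    molecules take large random steps each frame.  The returned ground
    truth is row-aligned (``molecule_id``, ``kind``, ``intensity_class``)
    plus a per-molecule table.

    ``max_blink_gap_frames`` caps the dark-frame length of blink gaps (set
    to the linking memory to guarantee no track fragmentation).
    """
    if mixture is None:
        raise InvalidParameterError("mixture must be provided")
    rng = np.random.default_rng(params.seed)
    n_b = params.n_molecules
    f = mixture.diffusing_fraction
    n_d = int(round(n_b * f / (1.0 - f))) if f > 0 else 0

    rows = []
    truth_rows = []
    molecules = []

    k_frames = _frame_counts(params, settings, rng).astype(int)
    for mid in range(n_b):
        x0, y0 = rng.uniform(0, mixture.fov_size, 2)
        k = int(min(k_frames[mid], settings.n_frames))
        start = int(rng.integers(0, max(1, settings.n_frames - k + 1)))
        visible = np.ones(k, dtype=bool)
        n_blinks = 0
        if params.blink_probability > 0 and rng.random() < params.blink_probability and k > 2:
            n_blinks = 1 + rng.geometric(1.0 / max(params.mean_blink_events, 1.0))
            for _ in range(n_blinks):
                gap = rng.exponential(params.blink_time_constant)
                g = int(gap // settings.interval_time)
                if max_blink_gap_frames is not None:
                    g = min(g, max_blink_gap_frames)
                if g == 0 or k <= g + 2:
                    continue
                pos = int(rng.integers(1, k - g))
                visible[pos:pos + g] = False
        is_multi = rng.random() < mixture.multi_fraction
        imu, isd = mixture.multi_intensity if is_multi else mixture.single_intensity
        frames_vis = start + np.flatnonzero(visible)
        for fr in frames_vis:
            rows.append((
                int(fr),
                x0 + rng.normal(0, mixture.localization_noise_sd),
                y0 + rng.normal(0, mixture.localization_noise_sd),
                max(rng.normal(*mixture.bound_sigma), 1.0),
                max(rng.normal(*mixture.bound_sigma), 1.0),
                rng.normal(imu, isd),
                rng.normal(*mixture.background),
            ))
            truth_rows.append((mid, "bound", "multi" if is_multi else "single"))
        molecules.append({
            "molecule_id": mid, "kind": "bound",
            "x": x0, "y": y0, "start_frame": start,
            "n_frames": k, "n_visible": int(visible.sum()),
            "n_blink_events": n_blinks,
            "intensity_class": "multi" if is_multi else "single",
        })

    for j in range(n_d):
        mid = n_b + j
        k = int(np.clip(math.ceil(rng.exponential(
            params.constant_exposure_bleach_time) / settings.exposure_time), 1,
            settings.n_frames))
        start = int(rng.integers(0, max(1, settings.n_frames - k + 1)))
        xx, yy = rng.uniform(0, mixture.fov_size, 2)
        for step in range(k):
            rows.append((
                start + step,
                xx, yy,
                max(rng.normal(*mixture.diffusing_sigma), 1.0),
                max(rng.normal(*mixture.diffusing_sigma), 1.0),
                rng.normal(*mixture.single_intensity),
                rng.normal(*mixture.background),
            ))
            truth_rows.append((mid, "diffusing", "single"))
            xx += rng.normal(0, mixture.diffusing_step_sd)
            yy += rng.normal(0, mixture.diffusing_step_sd)
        molecules.append({
            "molecule_id": mid, "kind": "diffusing",
            "x": xx, "y": yy, "start_frame": start,
            "n_frames": k, "n_visible": k, "n_blink_events": 0,
            "intensity_class": "single",
        })

    table = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    truth_df = pd.DataFrame(truth_rows, columns=["molecule_id", "kind", "intensity_class"])
    order = np.argsort(table["frame"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    truth_df = truth_df.iloc[order].reset_index(drop=True)
    ground_truth = {
        "rows": truth_df,
        "molecules": pd.DataFrame(molecules),
        "n_bound": n_b,
        "n_diffusing": n_d,
        "params": params,
        "mixture": mixture,
    }
    return table, ground_truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def gen_frap_traces(params: FrapSimParams) -> FrapTraceSet:
    """Simulate FRAP focus, whole-cell and control-focus intensity traces.

    Pre-bleach focus points have expectation 1.0 times the global bleaching
    decay; post-bleach points follow ``(c - a exp(-b t))`` times the decay.
    The decay is normalized to 1 at the first sampled time.
    """
    rng = np.random.default_rng(params.seed)
    t = params.sample_times
    n_pre = params.n_prebleach
    t0 = t[0]
    if math.isinf(params.global_bleach_time):
        decay = np.ones_like(t)
    else:
        decay = np.exp(-(t - t0) / params.global_bleach_time)

    focus_mean = np.concatenate([
        np.ones(n_pre),
        params.asymptote - params.amplitude * np.exp(-params.unbinding_rate * t[n_pre:]),
    ]) * decay
    cell_mean = np.concatenate([
        np.ones(n_pre),
        np.full(t.size - n_pre, params.cell_residual_fraction),
    ]) * decay
    control_mean = decay.copy()

    traces: list[FrapTrace] = []
    for i in range(params.n_traces):
        traces.append(FrapTrace(
            times=t.copy(),
            intensities=focus_mean + rng.normal(0, params.noise_sd, t.size),
            n_prebleach=n_pre, cell_id=f"cell{i:03d}", roi_type="focus",
        ))
        traces.append(FrapTrace(
            times=t.copy(),
            intensities=cell_mean + rng.normal(0, params.cell_noise_sd, t.size),
            n_prebleach=n_pre, cell_id=f"cell{i:03d}", roi_type="cell",
        ))
    for i in range(params.n_control):
        traces.append(FrapTrace(
            times=t.copy(),
            intensities=control_mean + rng.normal(0, params.noise_sd, t.size),
            n_prebleach=n_pre, cell_id=f"ctrl{i:03d}", roi_type="control_focus",
        ))
    truth = {
        "asymptote": params.asymptote,
        "amplitude": params.amplitude,
        "unbinding_rate": params.unbinding_rate,
        "bound_time": 1.0 / params.unbinding_rate,
        "global_bleach_time": params.global_bleach_time,
        "cell_residual_fraction": params.cell_residual_fraction,
        "focus_mean": focus_mean,
        "seed": params.seed,
    }
    return FrapTraceSet(traces=traces, ground_truth=truth)
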