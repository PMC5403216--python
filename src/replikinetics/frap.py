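"""FRAP recovery analysis for replisome foci.

After a focused bleach pulse at ``t = 0``, fluorescence at a replisome focus
recovers as unbleached molecules from the diffusing pool exchange with
bleached bound ones.  In the reaction-limited regime the recovery follows a
single exponential::

    y(t) = c - a * exp(-b * t)

where ``c`` is the recovery asymptote, ``a`` the recovery amplitude and
``b`` the unbinding rate ``k_off`` (bound time ``1/b``).  Traces are
filtered for clean bleaching, normalized to their pre-bleach mean, corrected
for global photobleaching using unbleached control foci, collated across
acquisition intervals and fitted by nonlinear least squares with the
asymptote bounded by the measured maximum possible recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, FitError, InputError

_EPS = 1e-9

TRACE_COLUMNS = ["time_s", "intensity", "cell_id", "roi_type"]
ROI_TYPES = ("focus", "cell", "control_focus")


@dataclass
class FrapTrace:
    """One ROI intensity time series; the bleach event is at ``t = 0``."""

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach: int
    cell_id: str = ""
    roi_type: str = "focus"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise InputError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.n_prebleach < 2:
            raise InputError("need at least two pre-bleach points")
        if self.n_prebleach >= self.times.size:
            raise InputError("trace has no post-bleach points")
        if self.roi_type not in ROI_TYPES:
            raise InputError(f"unknown roi_type {self.roi_type!r}")

    @property
    def pre_intensities(self) -> np.ndarray:
        return self.intensities[: self.n_prebleach]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach:]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.n_prebleach:]

    @property
    def bleach_value(self) -> float:
        """Intensity at the 0 s time point (first post-bleach frame)."""
        if abs(self.times[self.n_prebleach]) > 1e-6:
            raise InputError("trace has no 0 s time point")
        return float(self.intensities[self.n_prebleach])

    def replace_intensities(self, intensities: np.ndarray) -> "FrapTrace":
        return FrapTrace(self.times.copy(), np.asarray(intensities, dtype=float),
                         self.n_prebleach, self.cell_id, self.roi_type)


@dataclass
class BleachBaseline:
    """Exponential decay fitted to pre-bleach-normalized unbleached foci.

    The amplitude is kept as fitted (the control curve is normalized by its
    pre-bleach mean exactly like the FRAP traces, so dividing by this curve
    cancels the acquisition decay consistently).
    """

    rate: float  # per second, >= 0
    t0: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InputError("decay rate must be >= 0 (monotone non-increasing)")
        if self.amplitude <= 0:
            raise InputError("amplitude must be positive")

    def value(self, times: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -self.rate * (np.asarray(times, dtype=float) - self.t0))


@dataclass
class FrapFit:
    """Fitted reaction-limited recovery parameters."""

    c: float
    a: float
    b: float
    bound_time: float
    max_recovery: float
    ks_p: float
    status: str = "ok"  # "ok" | "not-estimable"
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    n_traces: int = 0
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "c": self.c, "a": self.a, "b": self.b,
            "bound_time": self.bound_time, "max_recovery": self.max_recovery,
            "ks_p": self.ks_p, "status": self.status,
            "se": self.se, "ci95": self.ci95,
            "n_traces": self.n_traces, "n_points": self.n_points,
        }


def recovery_model(t: np.ndarray, c: float, a: float, b: float) -> np.ndarray:
    """Reaction-limited recovery: ``y = c - a exp(-b t)`` (so ``y(0) = c - a``)."""
    return c - a * np.exp(-b * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# trace preparation
# ---------------------------------------------------------------------------


def filter_traces(traces: list[FrapTrace]) -> list[FrapTrace]:
    """Retain traces showing clean bleaching.

    A trace is kept only if every pre-bleach intensity exceeds the value of
    the ROI immediately after bleaching, and the 0 s intensity is below 40%
    of the mean pre-bleach intensity.
    """
    kept = []
    for tr in traces:
        i0 = tr.bleach_value
        pre = tr.pre_intensities
        if np.any(pre <= i0):
            continue
        if i0 >= 0.4 * pre.mean():
            continue
        kept.append(tr)
    return kept


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Divide a trace by its mean pre-bleach intensity (pre-bleach mean -> 1)."""
    m = float(trace.pre_intensities.mean())
    if m <= 0:
        raise InputError("non-positive pre-bleach mean")
    return trace.replace_intensities(trace.intensities / m)


def estimate_max_recovery(cell_traces: list[FrapTrace]) -> float:
    """Maximum possible recovery from whole-cell ROIs.

    The bleach pulse destroys a share of the cell's fluorophores, so a focus
    can at best recover to the whole-cell intensity remaining immediately
    after bleaching: mean over cells of (0 s intensity / pre-bleach mean).
    """
    if not cell_traces:
        raise InputError("need at least one whole-cell trace")
    ratios = [tr.bleach_value / tr.pre_intensities.mean() for tr in cell_traces]
    return float(np.mean(ratios))


def fit_bleach_baseline(control_traces: list[FrapTrace]) -> BleachBaseline:
    """Fit a global photobleaching decay from unbleached control foci.

    Each control trace is normalized to its pre-bleach mean, traces are
    averaged on the union of their time grids, and a single exponential
    ``A exp(-rate (t - t0))`` is fitted with free amplitude.
    """
    if not control_traces:
        raise InputError("need at least one control-focus trace")
    mean_trace = average_and_collate([normalize_trace(tr) for tr in control_traces])
    t = mean_trace.times
    y = mean_trace.intensities
    t0 = float(t[0])

    def model(tt, amp, rate):
        return amp * np.exp(-rate * (tt - t0))

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[float(y[0]), 1e-3],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitError(f"bleach-baseline fit failed: {exc}") from exc
    return BleachBaseline(rate=float(popt[1]), t0=t0, amplitude=float(popt[0]))


def correct_photobleach(trace: FrapTrace, baseline: BleachBaseline) -> FrapTrace:
    """Divide each time point by the normalized fitted bleaching decay."""
    vals = baseline.value(trace.times)
    if np.any(vals <= 0):
        raise InputError("baseline value must be positive over the trace span")
    return trace.replace_intensities(trace.intensities / vals)


def average_and_collate(traces: list[FrapTrace]) -> FrapTrace:
    """Pointwise mean of traces on the union of their time grids.

    Experiments captured with different intervals between pictures are
    collated into a single recovery curve; at each union time point the mean
    runs over the traces that sampled it.
    """
    if not traces:
        raise InputError("need at least one trace")
    all_times = np.unique(np.round(np.concatenate([tr.times for tr in traces]), 9))
    sums = np.zeros_like(all_times)
    counts = np.zeros_like(all_times)
    for tr in traces:
        idx = np.searchsorted(all_times, np.round(tr.times, 9))
        sums[idx] += tr.intensities
        counts[idx] += 1
    mean = sums / counts
    n_pre = int(np.sum(all_times < -1e-9))
    return FrapTrace(times=all_times, intensities=mean, n_prebleach=n_pre,
                     cell_id="mean", roi_type=traces[0].roi_type)


# ---------------------------------------------------------------------------
# recovery fitting
# ---------------------------------------------------------------------------


def _fit_post_bleach(t: np.ndarray, y: np.ndarray, c_upper: float) -> tuple[float, float, float]:
    c0 = float(np.clip(y[-1], 1e-6, c_upper * (1 - 1e-9)))
    a0 = float(np.clip(c0 - y[0], 1e-6, c_upper))
    span = max(float(t[-1] - t[0]), 1.0)
    b0 = 5.0 / span
    popt, _ = optimize.curve_fit(
        recovery_model, t, y, p0=[c0, a0, b0],
        bounds=([0.0, 0.0, 1e-9], [c_upper, c_upper, np.inf]),
        maxfev=20_000,
    )
    return tuple(float(v) for v in popt)


def fit_recovery(
    mean_trace: FrapTrace,
    max_recovery: float = 1.0,
    traces: list[FrapTrace] | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> FrapFit:
    """Fit the reaction-limited recovery model to a collated mean trace.

    Only post-bleach points (including 0 s) enter the least-squares fit; the
    asymptote ``c`` is bounded above by ``1.1 * max_recovery``.  Residual
    normality is assessed by a Kolmogorov-Smirnov test.  When the individual
    traces are supplied, SE and 95% CI per parameter come from bootstrap
    resampling whole traces (preserving per-cell correlation), recollating
    and refitting.  If the resulting unbinding-rate interval includes zero
    the fit is reported as not estimable (stable binder / pool-only signal).
    """
    t = mean_trace.post_times
    y = mean_trace.post_intensities
    if t.size < 5:
        raise InputError("need at least 5 post-bleach points")
    c_upper = 1.1 * max_recovery
    try:
        c, a, b = _fit_post_bleach(t, y, c_upper)
    except RuntimeError as exc:
        raise FitError(
            f"recovery fit did not converge (starting point c~{y[-1]:.3g})"
        ) from exc

    resid = y - recovery_model(t, c, a, b)
    sd = resid.std(ddof=1) if resid.size > 2 else 0.0
    if sd > 0:
        ks_p = float(stats.kstest((resid - resid.mean()) / sd, "norm").pvalue)
    else:
        ks_p = float("nan")

    se: dict = {}
    ci: dict = {}
    status = "ok"
    if traces:
        if n_boot < 100:
            raise ConfigurationError("n_boot must be >= 100")
        rng = np.random.default_rng(seed)
        boots = {k: [] for k in ("c", "a", "b", "bound_time")}
        n_tr = len(traces)
        for _ in range(n_boot):
            pick = rng.integers(0, n_tr, size=n_tr)
            resampled = average_and_collate([traces[i] for i in pick])
            try:
                cb, ab, bb = _fit_post_bleach(
                    resampled.post_times, resampled.post_intensities, c_upper)
            except RuntimeError:
                continue
            boots["c"].append(cb)
            boots["a"].append(ab)
            boots["b"].append(bb)
            boots["bound_time"].append(1.0 / bb if bb > 0 else np.inf)
        for k, v in boots.items():
            arr = np.asarray(v)
            fin = arr[np.isfinite(arr)]
            se[k] = float(fin.std(ddof=1)) if fin.size > 1 else 0.0
            ci[k] = [float(np.quantile(arr, 0.025)), float(np.quantile(arr, 0.975))]
        if ci.get("b") and ci["b"][0] <= 1e-6:
            status = "not-estimable"
        if ci.get("a") and ci["a"][0] <= 0.01:
            status = "not-estimable"
    # without bootstrap: a vanishing rate or amplitude means the trace is
    # indistinguishable from a non-recovering (stable-binder) focus
    if b < 1e-6 or a < 0.02:
        status = "not-estimable"

    return FrapFit(
        c=c, a=a, b=b,
        bound_time=(1.0 / b if b > 0 else math.inf),
        max_recovery=max_recovery, ks_p=ks_p, status=status,
        se=se, ci95=ci, n_traces=len(traces) if traces else 0,
        n_points=int(t.size),
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------


def traces_to_frame(traces: list[FrapTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for t, i in zip(tr.times, tr.intensities):
            rows.append({"time_s": t, "intensity": i,
                         "cell_id": tr.cell_id, "roi_type": tr.roi_type})
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def frame_to_traces(df: pd.DataFrame) -> list[FrapTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trace table missing columns: {missing}")
    traces = []
    for (cell, roi), grp in df.groupby(["cell_id", "roi_type"], sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        n_pre = int(np.sum(times < -1e-9))
        traces.append(FrapTrace(
            times=times, intensities=grp["intensity"].to_numpy(dtype=float),
            n_prebleach=n_pre, cell_id=str(cell), roi_type=str(roi),
        ))
    return traces
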