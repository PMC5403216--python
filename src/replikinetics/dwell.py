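"""Bound-time inference from single-molecule track durations.

A fluorescent focus disappears either because the molecule unbinds
(rate ``k_off = 1/T_bound``) or because its fluorophore photobleaches
(rate ``k_bleach = 1/T_bleach``).  Observed track durations are therefore
exponential with the summed rate::

    k_track = k_off + k_bleach        <=>    1/T_track = 1/T_bound + 1/T_bleach

Short tracks below the acceptance threshold are discarded, so durations are
modelled with a left-truncated exponential whose MLE for the mean beyond the
truncation point ``L`` is simply ``sample mean - L``.  The bleach time is
calibrated from a stable binder (a LacI-repressor-style control whose
unbinding is negligible on the experimental timescale) and rescaled between
protocols via the duty cycle.  The bound time follows by inverting the rate
sum::

    T_bound = T_track * T_bleach / (T_bleach - T_track)

Uncertainty is propagated by bootstrap (default 10,000 resamples, BCa
intervals) with the control sample resampled jointly when available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .acquisition import AcquisitionSettings, scaled_bleach_time
from .errors import (
    ConfigurationError,
    FitError,
    InputError,
    InsufficientDataError,
    UninformativeEstimateError,
)

DEFAULT_BOUND_TIME_BOUNDS = (1.0, 5400.0)
DEFAULT_TIMESCALE_BOUNDS = (0.1, 5400.0)
DEFAULT_BLEACH_VARIATION = 0.20
BLINK_CUTOFF = 2.6  # s; longer gaps are treated as new binding events

_EPS = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TrackDurationSample:
    """A set of track durations plus its truncation point and protocol.

    All durations must be >= the truncation point ``truncation_point`` (the
    minimum accepted duration implied by the min-localization threshold).
    """

    durations: np.ndarray
    truncation_point: float
    settings: AcquisitionSettings
    label: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.truncation_point < 0:
            raise InputError("truncation_point must be >= 0")
        if self.durations.size and self.durations.min() < self.truncation_point - _EPS:
            raise InputError(
                "all durations must be >= the truncation point "
                f"(min {self.durations.min()} < L={self.truncation_point})"
            )

    @property
    def n(self) -> int:
        return int(self.durations.size)


@dataclass
class ExponentialFit:
    """MLE of a left-truncated exponential: tau is the mean beyond L."""

    tau: float
    se: float
    ci95: tuple[float, float]
    log_likelihood: float
    n: int
    truncation_point: float = 0.0

    @property
    def bic(self) -> float:
        return math.log(self.n) - 2.0 * self.log_likelihood


@dataclass
class BleachCalibration:
    """Constant-exposure bleach time plus duty-cycle scaling.

    ``T_constant`` is the bleach time the fluorophore would have under
    continuous exposure; the effective bleach time under a protocol is
    ``(interval/exposure) * T_constant``.  The control sample is retained so
    bootstrap resampling can propagate calibration uncertainty.
    """

    t_constant: float
    control: TrackDurationSample | None = None
    frame_correction: bool = True

    def __post_init__(self) -> None:
        if not self.t_constant > 0:
            raise InputError("t_constant must be positive")

    def bleach_time(self, settings: AcquisitionSettings) -> float:
        return scaled_bleach_time(self.t_constant, settings)

    def table(self, settings_list: list[AcquisitionSettings]) -> dict[tuple[float, float], float]:
        return {
            (s.exposure_time, s.interval_time): self.bleach_time(s) for s in settings_list
        }


@dataclass
class BoundTimeEstimate:
    """Track time, bleach time and bleach-corrected bound time with errors."""

    t_track: float
    t_bleach: float
    t_bound: float
    se: float | None = None
    ci95: tuple[float, float] | None = None
    n: int = 0
    label: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_track(self) -> float:
        return 1.0 / self.t_track

    @property
    def k_bleach(self) -> float:
        return 1.0 / self.t_bleach

    @property
    def k_off(self) -> float:
        return 1.0 / self.t_bound

    def to_dict(self) -> dict:
        return {
            "t_track": self.t_track,
            "t_bleach": self.t_bleach,
            "t_bound": self.t_bound,
            "se": self.se,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "n": self.n,
            "label": self.label,
            "diagnostics": self.diagnostics,
        }


@dataclass
class TwoExpFit:
    """Left-truncated two-exponential mixture fit (tau1 <= tau2)."""

    p: float
    tau1: float
    tau2: float
    t_bound_alpha: float | None
    t_bound_beta: float | None
    log_likelihood: float
    bic: float
    llr_p_value: float
    n: int
    on_bounds: bool
    timescale_bounds: tuple[float, float]


@dataclass
class ModelSelection:
    choice: str  # "single" | "two"
    bic_single: float
    bic_two: float
    llr_p_value: float
    reasons: list[str]


@dataclass
class BlinkModel:
    """Fluorophore dark-gap model: exponential gap durations.

    ``blink_fraction`` is the fraction of molecules that blink at least once;
    ``cutoff`` is the longest gap still attributed to blinking rather than a
    new binding event.
    """

    gap_time_constant: float
    blink_fraction: float = 1.0
    cutoff: float = BLINK_CUTOFF
    memory: int = 1

    def __post_init__(self) -> None:
        if not self.gap_time_constant > 0:
            raise InputError("gap_time_constant must be positive")


# ---------------------------------------------------------------------------
# single-exponential MLE
# ---------------------------------------------------------------------------


def fit_truncated_exponential(sample: TrackDurationSample) -> ExponentialFit:
    """MLE of the left-truncated exponential: ``tau = mean(durations) - L``.

    The 95% CI uses the exact gamma sampling distribution of the mean of
    exponentials (``2 n tau_hat / tau ~ chi^2_{2n}``).

    Raises
    ------
    InputError
        If the sample is empty or any duration lies below L.
    FitError
        If ``mean - L`` is not positive (degenerate sample).
    """
    d = np.asarray(sample.durations, dtype=float)
    n = d.size
    if n < 1:
        raise InputError("need at least one duration")
    L = sample.truncation_point
    if d.min() < L - _EPS:
        raise InputError("duration below truncation point")
    tau = float(d.mean() - L)
    if tau <= 0:
        raise FitError("degenerate sample: mean duration equals the truncation point")
    ll = -n * math.log(tau) - float((d - L).sum()) / tau
    se = tau / math.sqrt(n)
    lo = 2 * n * tau / stats.chi2.ppf(0.975, 2 * n)
    hi = 2 * n * tau / stats.chi2.ppf(0.025, 2 * n)
    return ExponentialFit(tau=tau, se=se, ci95=(float(lo), float(hi)),
                          log_likelihood=float(ll), n=n, truncation_point=L)


def frame_corrected_tau(tau_raw: float | np.ndarray, interval: float):
    """Remove the frame-quantization bias from a continuous ``mean - L`` fit.

    Durations are whole multiples of the interval (geometric frame counts),
    for which ``mean - L = interval * q / (1 - q)`` with per-frame survival
    ``q = exp(-interval/tau)``.  Inverting gives the exact geometric MLE::

        tau = interval / log(1 + interval / (mean - L))

    which converges to the continuous estimate as ``interval -> 0``.
    """
    return interval / np.log1p(interval / tau_raw)


def estimate_track_time(
    sample: TrackDurationSample, frame_correction: bool = True
) -> tuple[float, ExponentialFit]:
    """Mean track duration beyond truncation, optionally de-quantized."""
    fit = fit_truncated_exponential(sample)
    tau = fit.tau
    if frame_correction:
        tau = float(frame_corrected_tau(tau, sample.settings.interval_time))
    return tau, fit


# ---------------------------------------------------------------------------
# bleach calibration and correction
# ---------------------------------------------------------------------------


def calibrate_bleach(
    control: TrackDurationSample, frame_correction: bool = True
) -> BleachCalibration:
    """Estimate the constant-exposure bleach time from a stable-binder control.

    The control's unbinding rate is negligible, so its mean track duration
    equals the effective bleach time under the control protocol; dividing by
    ``interval/exposure`` converts it to constant exposure.
    """
    tau, _ = estimate_track_time(control, frame_correction=frame_correction)
    t_constant = tau / control.settings.bleach_scaling
    return BleachCalibration(t_constant=t_constant, control=control,
                             frame_correction=frame_correction)


def correct_bound_time(t_track: float, t_bleach: float) -> float:
    """Invert the rate sum ``1/T_track = 1/T_bound + 1/T_bleach``.

    Raises
    ------
    UninformativeEstimateError
        If the track time is not strictly below the bleach time, in which
        case the bound time is not identifiable.
    """
    if not t_track > 0:
        raise InputError("t_track must be positive")
    if t_track >= t_bleach:
        raise UninformativeEstimateError(
            f"track time ({t_track:g} s) >= bleach time ({t_bleach:g} s): "
            "bound time not identifiable"
        )
    return t_track * t_bleach / (t_bleach - t_track)


def _safe_bound_time(t_track: np.ndarray, t_bleach: np.ndarray) -> np.ndarray:
    """Vectorized bound-time correction; non-identifiable entries -> +inf."""
    t_track = np.asarray(t_track, dtype=float)
    t_bleach = np.asarray(t_bleach, dtype=float)
    out = np.full(np.broadcast(t_track, t_bleach).shape, np.inf)
    ok = (t_track > 0) & (t_track < t_bleach)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = t_track * t_bleach / (t_bleach - t_track)
    out[ok] = np.broadcast_to(vals, out.shape)[ok]
    return out


# ---------------------------------------------------------------------------
# bootstrap with BCa intervals
# ---------------------------------------------------------------------------


def bca_interval(
    boot: np.ndarray,
    theta_hat: float,
    jackknife: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    ``boot`` may contain +inf entries (non-identifiable resamples); they sit
    in the upper tail and are handled by the quantile step.  A degenerate
    bootstrap distribution returns a zero-width interval at the estimate.
    """
    boot = np.asarray(boot, dtype=float)
    finite = boot[np.isfinite(boot)]
    if finite.size == 0:
        return (theta_hat, theta_hat)
    scale = max(1.0, abs(theta_hat))
    if np.ptp(finite) < 1e-12 * scale and finite.size == boot.size:
        return (theta_hat, theta_hat)
    B = boot.size
    prop = float(np.mean(boot < theta_hat))
    prop = min(max(prop, 1.0 / (B + 1)), 1.0 - 1.0 / (B + 1))
    z0 = stats.norm.ppf(prop)
    jack = np.asarray(jackknife, dtype=float)
    jack = jack[np.isfinite(jack)]
    if jack.size >= 2:
        jm = jack.mean()
        num = float(((jm - jack) ** 3).sum())
        den = 6.0 * float(((jm - jack) ** 2).sum()) ** 1.5
        a = num / den if den > 0 else 0.0
    else:
        a = 0.0
    lims = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = z0 + stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + z / (1.0 - a * z)) if a * z < 1.0 else 1.0 - 1e-12
        # quantile over the full bootstrap distribution, inf entries included
        lims.append(float(np.quantile(boot, float(np.clip(adj, 0.0, 1.0)))))
    return (lims[0], lims[1])


def bootstrap_estimate(
    sample: TrackDurationSample,
    calibration: BleachCalibration,
    n_boot: int = 10_000,
    method: str = "BCa",
    seed: int | None = None,
    frame_correction: bool = True,
) -> BoundTimeEstimate:
    """Point estimate and bootstrap SE/CI for the bleach-corrected bound time.

    Target durations are resampled with replacement; when the calibration
    carries its control sample, the control is resampled jointly so that
    bleach-calibration uncertainty propagates into the interval.  Resamples
    where the track time meets or exceeds the bleach time are recorded as
    non-identifiable (+inf) and counted in the diagnostics.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    if method not in ("BCa", "percentile"):
        raise ConfigurationError(f"unknown bootstrap method {method!r}")

    tau_track, fit = estimate_track_time(sample, frame_correction)
    t_bleach = calibration.bleach_time(sample.settings)
    t_bound = correct_bound_time(tau_track, t_bleach)

    rng = np.random.default_rng(seed)
    d = sample.durations
    n = d.size
    L = sample.truncation_point
    interval = sample.settings.interval_time

    def tau_from_means(means: np.ndarray, L: float, interval: float) -> np.ndarray:
        raw = means - L
        raw = np.where(raw > 0, raw, np.nan)
        if frame_correction:
            return np.asarray(frame_corrected_tau(raw, interval))
        return raw

    idx = rng.integers(0, n, size=(n_boot, n))
    tau_b = tau_from_means(d[idx].mean(axis=1), L, interval)

    control = calibration.control
    if control is not None and control.n >= 2:
        c = control.durations
        cidx = rng.integers(0, c.size, size=(n_boot, c.size))
        tau_cb = tau_from_means(
            c[cidx].mean(axis=1),
            control.truncation_point,
            control.settings.interval_time,
        )
        t_const_b = tau_cb / control.settings.bleach_scaling
        t_bleach_b = t_const_b * sample.settings.bleach_scaling
    else:
        t_bleach_b = np.full(n_boot, t_bleach)

    boot = _safe_bound_time(np.nan_to_num(tau_b, nan=np.inf), t_bleach_b)
    finite = boot[np.isfinite(boot)]
    n_invalid = int(n_boot - finite.size)
    se = float(finite.std(ddof=1)) if finite.size >= 2 else 0.0

    if method == "BCa":
        # jackknife over target durations (and control when resampled)
        loo_tau = tau_from_means((d.sum() - d) / (n - 1), L, interval) if n > 1 else np.array([tau_track])
        jack = _safe_bound_time(np.nan_to_num(loo_tau, nan=np.inf), t_bleach)
        if control is not None and control.n >= 2:
            c = control.durations
            loo_c = tau_from_means(
                (c.sum() - c) / (c.size - 1),
                control.truncation_point,
                control.settings.interval_time,
            )
            tb_loo = loo_c / control.settings.bleach_scaling * sample.settings.bleach_scaling
            jack = np.concatenate([jack, _safe_bound_time(tau_track, tb_loo)])
        ci = bca_interval(boot, t_bound, jack)
    else:
        if finite.size == n_boot and np.ptp(finite) < 1e-12 * max(1.0, abs(t_bound)):
            ci = (t_bound, t_bound)
        else:
            ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    return BoundTimeEstimate(
        t_track=tau_track,
        t_bleach=t_bleach,
        t_bound=t_bound,
        se=se,
        ci95=ci,
        n=n,
        label=sample.label,
        diagnostics={
            "method": method,
            "n_boot": n_boot,
            "n_invalid_resamples": n_invalid,
            "tau_track_raw": fit.tau,
            "frame_correction": frame_correction,
            "log_likelihood": fit.log_likelihood,
        },
    )


# ---------------------------------------------------------------------------
# constrained joint fit (near-bleach-limited binders)
# ---------------------------------------------------------------------------


def _trunc_exp_nll(durations: np.ndarray, L: float, tau: float, interval: float,
                   discrete: bool) -> float:
    """Negative log-likelihood of the truncated exponential (or its
    frame-quantized geometric counterpart) at mean-beyond-L ``tau``."""
    n = durations.size
    s = float((durations - L).sum())
    if not discrete:
        return n * math.log(tau) + s / tau
    # durations = (m + k) * interval with k >= 0 geometric(1-q)
    q = math.exp(-interval / tau)
    if not 0.0 < q < 1.0:
        return np.inf
    k_sum = s / interval
    return -(k_sum * math.log(q) + n * math.log(1.0 - q))


def constrained_fit(
    sample: TrackDurationSample,
    calibration: BleachCalibration,
    bound_time_bounds: tuple[float, float] = DEFAULT_BOUND_TIME_BOUNDS,
    bleach_variation: float = DEFAULT_BLEACH_VARIATION,
    initial: float | None = None,
    frame_correction: bool = True,
    n_boot: int = 0,
    seed: int | None = None,
) -> BoundTimeEstimate:
    """Joint box-constrained MLE of (T_bound, T_constant).

    For binders whose track durations approach the bleach time the plain
    inversion is unstable, so the bound time and the bleach constant are fit
    jointly by maximum likelihood: the target sample constrains the combined
    rate while the control sample (when available in the calibration) pins
    the bleach constant, which is allowed ``bleach_variation`` relative slack
    around its calibrated value.  The bound time is boxed (default 1 s to
    90 min) and estimates landing on a box edge are flagged.
    """
    lo_b, hi_b = bound_time_bounds
    if not 0 < lo_b < hi_b:
        raise ConfigurationError("invalid bound_time_bounds")
    t_const_hat = calibration.t_constant
    const_lo = t_const_hat * (1.0 - bleach_variation)
    const_hi = t_const_hat * (1.0 + bleach_variation)

    scale_t = sample.settings.bleach_scaling
    control = calibration.control
    interval = sample.settings.interval_time

    def nll(theta: np.ndarray, durations: np.ndarray, ctrl: np.ndarray | None) -> float:
        t_bound, t_const = theta
        t_bleach = t_const * scale_t
        tau_track = 1.0 / (1.0 / t_bound + 1.0 / t_bleach)
        total = _trunc_exp_nll(durations, sample.truncation_point, tau_track,
                               interval, frame_correction)
        if ctrl is not None:
            tau_c = t_const * control.settings.bleach_scaling
            total += _trunc_exp_nll(ctrl, control.truncation_point, tau_c,
                                    control.settings.interval_time,
                                    frame_correction)
        return total

    ctrl_d = control.durations if control is not None and control.n >= 2 else None

    if initial is None:
        tau0, _ = estimate_track_time(sample, frame_correction)
        t_bleach0 = calibration.bleach_time(sample.settings)
        if tau0 < t_bleach0:
            initial = float(np.clip(correct_bound_time(tau0, t_bleach0),
                                    lo_b * 1.001, hi_b * 0.999))
        else:
            initial = hi_b * 0.5
    elif not lo_b <= initial <= hi_b:
        raise InputError(f"initial estimate {initial:g} outside bound_time_bounds")
    x0 = np.array([float(np.clip(initial, lo_b * 1.001, hi_b * 0.999)), t_const_hat])

    def solve(durations: np.ndarray, ctrl: np.ndarray | None, x_init: np.ndarray):
        res = optimize.minimize(
            nll, x_init, args=(durations, ctrl), method="L-BFGS-B",
            bounds=[(lo_b, hi_b), (const_lo, const_hi)],
        )
        if not res.success and not np.isfinite(res.fun):
            raise FitError(f"constrained fit failed: {res.message}")
        return res

    res = solve(sample.durations, ctrl_d, x0)
    t_bound_hat, t_const_fit = map(float, res.x)
    t_bleach_fit = t_const_fit * scale_t
    tau_track_fit = 1.0 / (1.0 / t_bound_hat + 1.0 / t_bleach_fit)

    rel = 1e-3
    on_lower = t_bound_hat <= lo_b * (1 + rel)
    on_upper = t_bound_hat >= hi_b * (1 - rel)
    diagnostics = {
        "method": "constrained-mle",
        "converged": bool(res.success),
        "nll": float(res.fun),
        "at_lower_bound": bool(on_lower),
        "at_upper_bound": bool(on_upper),
        "bleach_at_bound": bool(
            t_const_fit <= const_lo * (1 + rel) or t_const_fit >= const_hi * (1 - rel)
        ),
        "bound_time_bounds": list(bound_time_bounds),
        "bleach_variation": bleach_variation,
        "frame_correction": frame_correction,
    }

    se = None
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            db = rng.choice(sample.durations, size=sample.n, replace=True)
            cb = (rng.choice(ctrl_d, size=ctrl_d.size, replace=True)
                  if ctrl_d is not None else None)
            try:
                vals[b] = solve(db, cb, res.x)["x"][0]
            except FitError:
                vals[b] = np.nan
        finite = vals[np.isfinite(vals)]
        se = float(finite.std(ddof=1)) if finite.size >= 2 else 0.0
        ci = (float(np.nanquantile(vals, 0.025)), float(np.nanquantile(vals, 0.975)))
        diagnostics["n_boot"] = n_boot

    return BoundTimeEstimate(
        t_track=tau_track_fit,
        t_bleach=t_bleach_fit,
        t_bound=t_bound_hat,
        se=se,
        ci95=ci,
        n=sample.n,
        label=sample.label,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# two-exponential mixture and model selection
# ---------------------------------------------------------------------------


def _two_exp_nll(theta: np.ndarray, shifted: np.ndarray) -> float:
    p, t1, t2 = theta
    with np.errstate(divide="ignore"):
        la = math.log(p) if p > 0 else -np.inf
        lb = math.log1p(-p) if p < 1 else -np.inf
        comp = np.stack([
            la - math.log(t1) - shifted / t1,
            lb - math.log(t2) - shifted / t2,
        ])
    return -float(logsumexp(comp, axis=0).sum())


def fit_two_exponential(
    sample: TrackDurationSample,
    calibration: BleachCalibration | None = None,
    timescale_bounds: tuple[float, float] = DEFAULT_TIMESCALE_BOUNDS,
    n_starts: int = 6,
) -> TwoExpFit:
    """MLE of a left-truncated two-exponential mixture.

    The two observed timescales are each the harmonic composition of a bound
    time with the bleach time; when a calibration is given the component
    bound times are recovered by inverting that relation.  Constraining
    ``p = 1`` recovers the single-exponential model, making the
    log-likelihood-ratio test against it well defined.
    """
    if sample.n < 10:
        raise InputError("need at least 10 durations for a mixture fit")
    lo, hi = timescale_bounds
    shifted = sample.durations - sample.truncation_point
    n = sample.n
    tau_hat = max(float(shifted.mean()), lo * 1.01)

    med = float(np.median(shifted))
    lower = shifted[shifted <= med]
    upper = shifted[shifted > med]
    t_lo = float(lower.mean()) if lower.size else tau_hat * 0.3
    t_hi = float(upper.mean()) if upper.size else tau_hat * 3.0
    starts = [
        (0.5, max(t_lo, lo * 1.01), min(max(t_hi, t_lo * 1.5), hi * 0.99)),
        (0.5, max(tau_hat * 0.3, lo * 1.01), min(tau_hat * 3.0, hi * 0.99)),
        (0.3, max(tau_hat * 0.2, lo * 1.01), min(tau_hat * 2.0, hi * 0.99)),
        (0.7, max(tau_hat * 0.5, lo * 1.01), min(tau_hat * 5.0, hi * 0.99)),
        (0.9, max(tau_hat * 0.9, lo * 1.01), min(tau_hat * 1.2, hi * 0.99)),
        (0.1, max(tau_hat * 0.1, lo * 1.01), min(tau_hat * 1.1, hi * 0.99)),
    ][:n_starts]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _two_exp_nll, np.array(x0), args=(shifted,), method="L-BFGS-B",
            bounds=[(1e-6, 1.0 - 1e-6), (lo, hi), (lo, hi)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("two-exponential fit did not converge")

    p, t1, t2 = map(float, best.x)
    if t1 > t2:
        t1, t2, p = t2, t1, 1.0 - p
    ll2 = -float(best.fun)

    single = fit_truncated_exponential(sample)
    llr = max(0.0, 2.0 * (ll2 - single.log_likelihood))
    p_val = float(stats.chi2.sf(llr, df=2))
    bic2 = 3.0 * math.log(n) - 2.0 * ll2

    rel = 1e-3
    on_bounds = any(
        t <= lo * (1 + rel) or t >= hi * (1 - rel) for t in (t1, t2)
    )

    tba = tbb = None
    if calibration is not None:
        t_bleach = calibration.bleach_time(sample.settings)
        tba = t1 * t_bleach / (t_bleach - t1) if t1 < t_bleach else None
        tbb = t2 * t_bleach / (t_bleach - t2) if t2 < t_bleach else None

    return TwoExpFit(
        p=p, tau1=t1, tau2=t2, t_bound_alpha=tba, t_bound_beta=tbb,
        log_likelihood=ll2, bic=bic2, llr_p_value=p_val, n=n,
        on_bounds=on_bounds, timescale_bounds=timescale_bounds,
    )


def select_model(
    single: ExponentialFit, two: TwoExpFit, alpha: float = 0.01
) -> ModelSelection:
    """Choose between single- and two-exponential binding models.

    The two-exponential model is accepted only when (i) its BIC is lower,
    (ii) the likelihood-ratio test rejects the single model at ``alpha``,
    and (iii) neither timescale sits on a fitting bound.
    """
    reasons = []
    if two.bic >= single.bic:
        reasons.append("BIC favours single-exponential")
    if two.llr_p_value >= alpha:
        reasons.append(f"LLR p={two.llr_p_value:.3g} >= {alpha}")
    if two.on_bounds:
        reasons.append("two-exponential timescale pegged at a fitting bound")
    choice = "two" if not reasons else "single"
    return ModelSelection(
        choice=choice, bic_single=single.bic, bic_two=two.bic,
        llr_p_value=two.llr_p_value, reasons=reasons,
    )


# ---------------------------------------------------------------------------
# averaging across experiments
# ---------------------------------------------------------------------------


def weighted_average(estimates: list[BoundTimeEstimate]) -> BoundTimeEstimate:
    """Inverse-variance weighted average of bound-time estimates.

    Estimates missing an SE trigger a fallback to weighting by sample size
    (with a warning).  The combined SE is ``sqrt(1/sum(w))`` under
    inverse-variance weights.
    """
    if not estimates:
        raise InputError("need at least one estimate")
    if len(estimates) == 1:
        return estimates[0]
    vals = np.array([e.t_bound for e in estimates])
    ses = [e.se for e in estimates]
    if any(s is None or s <= 0 for s in ses):
        warnings.warn("missing SEs: falling back to n-weighting", stacklevel=2)
        w = np.array([max(e.n, 1) for e in estimates], dtype=float)
        mean = float(np.average(vals, weights=w))
        se = None
    else:
        w = 1.0 / np.array(ses, dtype=float) ** 2
        mean = float(np.average(vals, weights=w))
        se = float(math.sqrt(1.0 / w.sum()))
    t_bleach = float(np.average([e.t_bleach for e in estimates],
                                weights=w))
    t_track = 1.0 / (1.0 / mean + 1.0 / t_bleach)
    return BoundTimeEstimate(
        t_track=t_track, t_bleach=t_bleach, t_bound=mean, se=se,
        ci95=(mean - 1.96 * se, mean + 1.96 * se) if se is not None else None,
        n=int(sum(e.n for e in estimates)),
        label="weighted-average",
        diagnostics={"inputs": [e.to_dict() for e in estimates]},
    )


# ---------------------------------------------------------------------------
# blinking
# ---------------------------------------------------------------------------


def analyze_blinking(
    gap_times: np.ndarray,
    exposure: float,
    cutoff: float = BLINK_CUTOFF,
    blink_fraction: float = 1.0,
    memory: int = 1,
) -> BlinkModel:
    """Fit the dark-gap time constant from observed blink gaps.

    Gaps shorter than one exposure are unobservable (the molecule reappears
    within the same frame) and gaps above ``cutoff`` are treated as new
    binding events, so the likelihood is a doubly truncated exponential on
    ``[exposure, cutoff]`` whose MLE is found by solving the mean equation.
    """
    if not exposure > 0:
        raise InputError("exposure must be positive")
    if cutoff <= exposure:
        raise InputError("cutoff must exceed the exposure time")
    g = np.asarray(gap_times, dtype=float)
    obs = g[(g >= exposure - _EPS) & (g <= cutoff + _EPS)]
    if obs.size == 0:
        raise InsufficientDataError("no gaps between the exposure time and the cutoff")
    m = float(obs.mean())
    width = cutoff - exposure

    def mean_eq(tau: float) -> float:
        z = width / tau
        # for tau << width the upper truncation is irrelevant
        tail = 0.0 if z > 700 else width / math.expm1(z)
        return exposure + tau - tail - m

    # the truncated mean rises from `exposure` to the window midpoint
    if m >= exposure + width / 2.0 - 1e-12:
        raise FitError("gap mean at the truncation-window midpoint: time constant unbounded")
    tau = float(optimize.brentq(mean_eq, 1e-6, 1e6))
    return BlinkModel(gap_time_constant=tau, blink_fraction=blink_fraction,
                      cutoff=cutoff, memory=memory)


def premature_termination_probability(
    model: BlinkModel, interval: float, memory: int | None = None
) -> float:
    """Probability that blinking prematurely terminates a track.

    A track is cut when a dark gap outlives the linking memory window
    ``memory * interval``; under the exponential gap model that tail
    probability is ``exp(-window/tau)``, scaled by the fraction of molecules
    that blink at all.  Decreases monotonically with the interval.
    """
    if not interval > 0:
        raise InputError("interval must be positive")
    mem = model.memory if memory is None else memory
    window = mem * interval
    if math.isinf(window):
        return 0.0
    return model.blink_fraction * math.exp(-window / model.gap_time_constant)
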