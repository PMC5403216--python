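"""Localization-table tracking and single-molecule track filtering.

Localizations (one fitted spot per frame) are linked into tracks by
nearest-neighbour association within a search radius, with a short memory to
bridge blinking.  Tracks are then refined to immobile single molecules:

* a two-component Gaussian mixture on PSF widths separates bound (sharp)
  from diffusing (motion-blurred) molecules, giving width thresholds;
* a per-interval minimum-localization threshold removes short, unreliable
  tracks and defines the truncation point for downstream dwell-time MLE;
* a Gaussian mixture on mean track intensities isolates the single-molecule
  brightness cluster from multi-molecule (and out-of-focus) clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .acquisition import AcquisitionSettings
from .dwell import TrackDurationSample
from .errors import ConfigurationError, FitError, InputError

DEFAULT_LINK_RADIUS = 300.0  # nm
DEFAULT_MEMORY = 1  # frames a molecule may go dark and still be linked
DEFAULT_FRAGMENT_GAP = 4  # frames, for fragment re-linkage of long-lived binders
DEFAULT_PSF_THRESHOLD_X = 170.0  # nm, on the mean PSF sigma over a track
DEFAULT_PSF_THRESHOLD_Y = 215.0  # nm

# minimum accepted localizations per track, keyed by interval time (s)
MIN_LOCALIZATIONS = {0.5: 4, 1.0: 4, 2.0: 3, 5.0: 2, 10.0: 2}

LOCALIZATION_COLUMNS = [
    "frame", "x_nm", "y_nm", "sigma_x_nm", "sigma_y_nm", "intensity", "background",
]


@dataclass
class Track:
    """An ordered run of localizations attributed to one molecule."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    intensity: np.ndarray
    localization_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size == 0:
            raise InputError("a track needs at least one localization")
        if np.any(np.diff(self.frames) <= 0):
            raise InputError("track frames must be strictly increasing")

    @property
    def n_localizations(self) -> int:
        return int(self.frames.size)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def mean_x(self) -> float:
        return float(np.mean(self.x))

    @property
    def mean_y(self) -> float:
        return float(np.mean(self.y))

    @property
    def mean_sigma_x(self) -> float:
        return float(np.mean(self.sigma_x))

    @property
    def mean_sigma_y(self) -> float:
        return float(np.mean(self.sigma_y))

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity))

    def duration(self, interval_time: float, convention: str = "n") -> float:
        """Track duration in seconds.

        ``convention="n"`` (default) counts one interval per localization,
        matching the truncation point ``min_localizations * interval``;
        ``"n-1"`` counts inter-localization intervals only.
        """
        if convention == "n":
            return self.n_localizations * interval_time
        if convention == "n-1":
            return (self.n_localizations - 1) * interval_time
        raise ConfigurationError(f"unknown duration convention {convention!r}")


@dataclass
class MixtureFit:
    """Two- (or k-) component 1-D Gaussian mixture MLE.

    Components are sorted by ascending mean; ``p`` is the weight of the
    first (smallest-mean) component, labelled "bound" for PSF widths and
    "single-molecule" candidates for intensities.
    """

    p: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    log_likelihood: float
    n_components: int
    bic: float
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    sds: np.ndarray = field(default_factory=lambda: np.array([]))
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def threshold(self, n_sd: float = 2.0) -> float:
        """Data-driven cut for the bound component: ``mu1 + n_sd * sigma1``."""
        return self.mu1 + n_sd * self.sigma1


def read_localization_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"localization table missing columns: {missing}")
    return table


def write_localization_table(table: pd.DataFrame, path) -> None:
    table[LOCALIZATION_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def link_localizations(
    table: pd.DataFrame,
    radius: float = DEFAULT_LINK_RADIUS,
    memory: int = DEFAULT_MEMORY,
) -> list[Track]:
    """Nearest-neighbour frame-to-frame linking with a blink memory.

    A localization joins an existing track if it lies within ``radius`` nm of
    the track's last position and the track has been dark for at most
    ``memory`` frames.  Conflicts are resolved greedily by ascending
    distance, ties by lower localization index; unmatched localizations seed
    new tracks, so every localization belongs to exactly one track.
    """
    if radius <= 0:
        raise InputError("radius must be positive")
    if memory < 0:
        raise InputError("memory must be >= 0")
    frames = table["frame"].to_numpy()
    if frames.size and np.any(np.diff(frames) < 0):
        raise InputError("localization table must be sorted by frame")

    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)

    # open tracks: lists of localization row indices
    open_tracks: list[dict] = []
    done: list[list[int]] = []
    order = np.arange(frames.size)

    for f in np.unique(frames):
        rows = order[frames == f]
        # retire tracks dark for longer than the memory window
        still_open = []
        for t in open_tracks:
            if f - t["last_frame"] - 1 > memory:
                done.append(t["rows"])
            else:
                still_open.append(t)
        open_tracks = still_open

        candidates = [t for t in open_tracks if t["last_frame"] < f]
        pairs = []
        for ti, t in enumerate(candidates):
            dx = x[rows] - t["last_x"]
            dy = y[rows] - t["last_y"]
            dist = np.hypot(dx, dy)
            for rj, dj in zip(rows, dist):
                if dj <= radius:
                    pairs.append((float(dj), int(rj), ti))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_rows: set[int] = set()
        used_tracks: set[int] = set()
        for dj, rj, ti in pairs:
            if rj in used_rows or ti in used_tracks:
                continue
            used_rows.add(rj)
            used_tracks.add(ti)
            t = candidates[ti]
            t["rows"].append(rj)
            t["last_frame"] = f
            t["last_x"] = x[rj]
            t["last_y"] = y[rj]
        for rj in rows:
            if int(rj) not in used_rows:
                open_tracks.append({
                    "rows": [int(rj)], "last_frame": f,
                    "last_x": x[rj], "last_y": y[rj],
                })
    done.extend(t["rows"] for t in open_tracks)
    done.sort(key=lambda rows_: (frames[rows_[0]], rows_[0]))

    tracks = []
    for tid, rows_ in enumerate(done):
        idx = np.array(rows_, dtype=int)
        tracks.append(Track(
            track_id=tid,
            frames=frames[idx],
            x=x[idx],
            y=y[idx],
            sigma_x=table["sigma_x_nm"].to_numpy(dtype=float)[idx],
            sigma_y=table["sigma_y_nm"].to_numpy(dtype=float)[idx],
            intensity=table["intensity"].to_numpy(dtype=float)[idx],
            localization_indices=idx,
        ))
    return tracks


def link_track_fragments(
    tracks: list[Track],
    max_gap: int = DEFAULT_FRAGMENT_GAP,
    radius: float = DEFAULT_LINK_RADIUS,
) -> list[Track]:
    """Merge track fragments of long-lived binders.

    Fragments whose mean positions are within ``radius`` nm and separated by
    at most ``max_gap`` frames are merged, transitively in frame order.
    Used for species whose tracks outlive transient detection drop-outs
    (out-of-focus excursions longer than the linking memory).
    """
    if max_gap < 0:
        raise InputError("max_gap must be >= 0")
    remaining = sorted(tracks, key=lambda t: (t.start_frame, t.track_id))
    merged: list[Track] = []
    consumed = [False] * len(remaining)
    for i, t in enumerate(remaining):
        if consumed[i]:
            continue
        current = t
        while True:
            best_j = None
            best_key = None
            for j in range(i + 1, len(remaining)):
                if consumed[j]:
                    continue
                nxt = remaining[j]
                gap = nxt.start_frame - current.end_frame - 1
                if gap < 0 or gap > max_gap:
                    continue
                d = math.hypot(nxt.mean_x - current.mean_x,
                               nxt.mean_y - current.mean_y)
                if d > radius:
                    continue
                key = (nxt.start_frame, d)
                if best_key is None or key < best_key:
                    best_key, best_j = key, j
            if best_j is None:
                break
            nxt = remaining[best_j]
            consumed[best_j] = True
            current = Track(
                track_id=current.track_id,
                frames=np.concatenate([current.frames, nxt.frames]),
                x=np.concatenate([current.x, nxt.x]),
                y=np.concatenate([current.y, nxt.y]),
                sigma_x=np.concatenate([current.sigma_x, nxt.sigma_x]),
                sigma_y=np.concatenate([current.sigma_y, nxt.sigma_y]),
                intensity=np.concatenate([current.intensity, nxt.intensity]),
                localization_indices=np.concatenate(
                    [current.localization_indices, nxt.localization_indices]),
            )
        merged.append(current)
    return merged


# ---------------------------------------------------------------------------
# mixture fits
# ---------------------------------------------------------------------------


def _gaussian_mixture_fit(values: np.ndarray, n_components: int,
                          random_state: int = 0) -> tuple[GaussianMixture, MixtureFit]:
    values = np.asarray(values, dtype=float)
    if values.size < 2 * n_components:
        raise InputError(
            f"need at least {2 * n_components} values for a {n_components}-component fit"
        )
    if np.ptp(values) == 0:
        raise FitError("degenerate input: all values identical")
    X = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components, covariance_type="full", n_init=10,
        max_iter=1000, tol=1e-8, random_state=random_state, reg_covar=1e-10,
    ).fit(X)
    if not gm.converged_:
        raise FitError(
            f"EM did not converge in {gm.n_iter_} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    ll = float(gm.score(X) * values.size)
    fit = MixtureFit(
        p=float(weights[0]),
        mu1=float(means[0]), sigma1=float(sds[0]),
        mu2=float(means[1]) if n_components > 1 else float("nan"),
        sigma2=float(sds[1]) if n_components > 1 else float("nan"),
        log_likelihood=ll, n_components=n_components, bic=float(gm.bic(X)),
        means=means, sds=sds, weights=weights,
    )
    return gm, fit


def fit_psf_mixture(values: np.ndarray, n_components: int = 2,
                    random_state: int = 0) -> MixtureFit:
    """Two-component Gaussian mixture MLE on PSF widths (nm).

    The smaller-mean component represents bound (immobile, diffraction
    limited) molecules; ``fit.threshold()`` gives the mean + 2 sd width cut.
    """
    _, fit = _gaussian_mixture_fit(values, n_components, random_state)
    return fit


def filter_immobile(
    tracks: list[Track],
    threshold_x: float = DEFAULT_PSF_THRESHOLD_X,
    threshold_y: float = DEFAULT_PSF_THRESHOLD_Y,
) -> list[Track]:
    """Keep tracks whose mean PSF widths fall below both axis thresholds."""
    if threshold_x <= 0 or threshold_y <= 0:
        raise InputError("thresholds must be positive")
    return [
        t for t in tracks
        if t.mean_sigma_x <= threshold_x and t.mean_sigma_y <= threshold_y
    ]


def apply_min_localization_threshold(
    tracks: list[Track],
    interval_time: float,
    min_localizations: int | None = None,
) -> tuple[list[Track], float]:
    """Drop short tracks and return the implied truncation point.

    The per-interval minimum (4, 4, 3, 2, 2 localizations at 0.5, 1, 2, 5,
    10 s) reflects that longer intervals make a detected track more likely to
    be a genuinely bound molecule.  The truncation point for downstream MLE
    is ``min_localizations * interval_time``.
    """
    if min_localizations is None:
        for key, val in MIN_LOCALIZATIONS.items():
            if math.isclose(interval_time, key, rel_tol=1e-6):
                min_localizations = val
                break
        else:
            raise ConfigurationError(
                f"no min-localization threshold configured for interval {interval_time} s"
            )
    kept = [t for t in tracks if t.n_localizations >= min_localizations]
    return kept, min_localizations * interval_time


def fit_intensity_gmm(
    tracks: list[Track],
    n_components: int | None = None,
    random_state: int = 0,
) -> tuple[MixtureFit, list[Track]]:
    """Isolate single-molecule tracks by mean-intensity Gaussian mixture.

    Tracks are clustered by EM membership probability.  With 2 components
    the lowest-mean cluster is returned as single molecules; with 3 (used
    when an out-of-focus low-intensity spike is present) the second-lowest.
    When ``n_components`` is None both are fit and the lower BIC wins.
    """
    if len(tracks) < 10:
        raise InputError("need at least 10 tracks for the intensity mixture")
    values = np.array([t.mean_intensity for t in tracks])
    if n_components is None:
        fits = {}
        for k in (2, 3):
            try:
                fits[k] = _gaussian_mixture_fit(values, k, random_state)
            except (FitError, InputError):
                continue
        if not fits:
            raise FitError("intensity mixture failed for 2 and 3 components")
        n_components = min(fits, key=lambda k: fits[k][1].bic)
        gm, fit = fits[n_components]
    elif n_components in (2, 3):
        gm, fit = _gaussian_mixture_fit(values, n_components, random_state)
    else:
        raise ConfigurationError("n_components must be 2 or 3")

    labels = gm.predict(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    target = order[0] if n_components == 2 else order[1]
    singles = [t for t, lab in zip(tracks, labels) if lab == target]
    return fit, singles


# ---------------------------------------------------------------------------
# rebinding
# ---------------------------------------------------------------------------


def detect_rebinding(
    tracks: list[Track],
    interval_time: float,
    radius: float = DEFAULT_LINK_RADIUS,
) -> list[float]:
    """Gap times between a track's end and the next track at the same spot.

    For every ordered pair (track end, next track start) whose mean
    positions are within ``radius`` nm, emits the intervening time
    ``(start - end) * interval`` in seconds.  No minimum-localization
    threshold is applied here: the input is whatever track list the caller
    considers binding events.
    """
    by_start = sorted(tracks, key=lambda t: (t.start_frame, t.track_id))
    gaps: list[float] = []
    for t in tracks:
        best = None
        for nxt in by_start:
            if nxt.start_frame <= t.end_frame:
                continue
            d = math.hypot(nxt.mean_x - t.mean_x, nxt.mean_y - t.mean_y)
            if d > radius:
                continue
            if best is None or nxt.start_frame < best.start_frame:
                best = nxt
        if best is not None:
            gaps.append((best.start_frame - t.end_frame) * interval_time)
    return gaps


# ---------------------------------------------------------------------------
# track durations
# ---------------------------------------------------------------------------


def tracks_to_duration_sample(
    tracks: list[Track],
    settings: AcquisitionSettings,
    truncation_point: float,
    label: str = "",
    convention: str = "n",
) -> TrackDurationSample:
    """Collect track durations into a sample for dwell-time inference."""
    durations = np.array([t.duration(settings.interval_time, convention) for t in tracks])
    return TrackDurationSample(
        durations=durations, truncation_point=truncation_point,
        settings=settings, label=label,
    )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """One row per localization with its track id (CSV serialization)."""
    rows = []
    for t in tracks:
        for i in range(t.n_localizations):
            rows.append({
                "track_id": t.track_id, "frame": int(t.frames[i]),
                "x_nm": t.x[i], "y_nm": t.y[i],
                "sigma_x_nm": t.sigma_x[i], "sigma_y_nm": t.sigma_y[i],
                "intensity": t.intensity[i],
            })
    return pd.DataFrame(rows)


def track_summaries(tracks: list[Track], interval_time: float) -> list[dict]:
    return [
        {
            "track_id": t.track_id,
            "start_frame": t.start_frame,
            "end_frame": t.end_frame,
            "n_localizations": t.n_localizations,
            "mean_x": t.mean_x,
            "mean_y": t.mean_y,
            "mean_sigma_x": t.mean_sigma_x,
            "mean_sigma_y": t.mean_sigma_y,
            "mean_intensity": t.mean_intensity,
            "duration_s": t.duration(interval_time),
        }
        for t in tracks
    ]
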