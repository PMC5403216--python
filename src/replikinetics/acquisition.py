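"""Camera acquisition settings for single-molecule time-lapse imaging.

Bound molecules are imaged with long exposures (to motion-blur the diffusing
pool) spaced by an interval at least as long as the exposure.  The duty cycle
``exposure/interval`` controls how fast fluorophores photobleach in wall-clock
time: bleaching is driven by accumulated light exposure, so stroboscopic
imaging stretches the effective bleach time by ``interval/exposure``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class AcquisitionSettings:
    """Exposure/interval protocol of one sptPALM acquisition.

    Parameters
    ----------
    exposure_time
        Camera exposure per frame, seconds.
    interval_time
        Time between consecutive frame starts, seconds.  Must be at least
        the exposure time (continuous illumination when equal).
    n_frames
        Number of frames in the movie.
    pixel_size
        Camera pixel size in nm (metadata only; positions are stored in nm).
    """

    exposure_time: float
    interval_time: float
    n_frames: int = 600
    pixel_size: float = 100.0

    def __post_init__(self) -> None:
        if not self.exposure_time > 0:
            raise InvalidParameterError("exposure_time must be positive")
        if self.interval_time < self.exposure_time:
            raise InvalidParameterError(
                "interval_time must be >= exposure_time "
                f"({self.interval_time} < {self.exposure_time})"
            )
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")

    @property
    def duty_cycle(self) -> float:
        """Fraction of each interval the camera is exposing."""
        return self.exposure_time / self.interval_time

    @property
    def bleach_scaling(self) -> float:
        """Factor by which stroboscopic imaging stretches the bleach time.

        The effective bleach time under this protocol is
        ``bleach_scaling * T_constant`` where ``T_constant`` is the bleach
        time under continuous exposure.
        """
        return self.interval_time / self.exposure_time

    def to_dict(self) -> dict:
        return {
            "exposure_time": self.exposure_time,
            "interval_time": self.interval_time,
            "n_frames": self.n_frames,
            "pixel_size": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSettings":
        return cls(**{k: d[k] for k in ("exposure_time", "interval_time", "n_frames", "pixel_size") if k in d})


def scaled_bleach_time(t_constant: float, settings: AcquisitionSettings) -> float:
    """Effective bleach time under a stroboscopic protocol.

    ``T_bleach = (interval / exposure) * T_constant``: photobleaching depends
    on accumulated exposure, so spacing exposures out slows it down in
    wall-clock time by the inverse duty cycle.
    """
    if not t_constant > 0:
        raise InvalidParameterError("t_constant must be positive")
    return settings.bleach_scaling * t_constant
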