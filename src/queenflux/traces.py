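"""Core per-cell time-series containers.

All traces live on a uniform time grid: frame ``k`` is acquired at
``k * frame_interval`` minutes.  Containers are thin wrappers around numpy
arrays; tabular I/O (tidy CSV) lives in :mod:`queenflux.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["RatioTrace", "ChannelTraces", "AggregationTrace"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must not be empty")
    return arr


@dataclass
class RatioTrace:
    """Per-cell excitation-ratio time series of the QUEEN ATP biosensor.

    The mean in-cell ratio at each frame is the cell's ATP readout.  ``atp``
    (mM) is filled by :func:`queenflux.ratiometry.ratio_to_atp` once a
    calibration is supplied.  ``corrected_frames`` records acquisition-error
    frames repaired by adjacent-frame averaging.
    """

    cell_id: str
    ratio: np.ndarray
    frame_interval: float  # minutes
    atp: np.ndarray | None = None
    corrected_frames: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ratio = _as_float_array(self.ratio, "ratio")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio must be finite at every frame")
        if self.atp is not None:
            self.atp = _as_float_array(self.atp, "atp")
            if self.atp.size != self.ratio.size:
                raise ValueError("atp and ratio must have equal length")
        bad = [k for k in self.corrected_frames if not 0 <= k < self.ratio.size]
        if bad:
            raise ValueError(f"corrected_frames out of range: {bad}")
        self.corrected_frames = tuple(sorted(set(int(k) for k in self.corrected_frames)))

    @property
    def n_frames(self) -> int:
        return int(self.ratio.size)

    @property
    def time(self) -> np.ndarray:
        """Acquisition times in minutes (uniform grid starting at 0)."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    @property
    def span_min(self) -> float:
        """Observation span in minutes (first to last frame)."""
        return float((self.n_frames - 1) * self.frame_interval)

    def with_ratio(self, ratio: np.ndarray, **changes) -> "RatioTrace":
        return replace(self, ratio=np.asarray(ratio, dtype=float), **changes)

    def to_frame(self) -> pd.DataFrame:
        corrected = np.zeros(self.n_frames, dtype=bool)
        corrected[list(self.corrected_frames)] = True
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(self.n_frames),
                "time_min": self.time,
                "ratio": self.ratio,
                "atp_mM": self.atp if self.atp is not None else np.nan,
                "corrected": corrected,
            }
        )


@dataclass
class ChannelTraces:
    """Per-cell mean fluorescence under the two sensor excitations.

    ``ex410`` is the ATP-sensitive excitation; ``ex490`` the reference.
    Intensities are arbitrary camera units and must be non-negative.
    """

    cell_id: str
    ex410: np.ndarray
    ex490: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.ex410 = _as_float_array(self.ex410, "ex410")
        self.ex490 = _as_float_array(self.ex490, "ex490")
        if self.ex410.size != self.ex490.size:
            raise ValueError("ex410 and ex490 must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if np.any(self.ex410 < 0) or np.any(self.ex490 < 0):
            raise ValueError("channel intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.ex410.size)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


@dataclass
class AggregationTrace:
    """Per-cell mean intensity of the aggregate reporter (Hsp104 fusion).

    Shares the time grid of the cell's :class:`RatioTrace` when paired.
    """

    cell_id: str
    mean_intensity: np.ndarray
    frame_interval: float
    foci_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_intensity = _as_float_array(self.mean_intensity, "mean_intensity")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.mean_intensity)):
            raise ValueError("mean_intensity must be finite")
        if self.foci_count is not None:
            self.foci_count = np.asarray(self.foci_count, dtype=int)
            if self.foci_count.size != self.mean_intensity.size:
                raise ValueError("foci_count and mean_intensity must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.mean_intensity.size)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(self.n_frames),
                "time_min": self.time,
                "reporter_mean": self.mean_intensity,
            }
        )
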