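"""Position traces and spike trains.

A :class:`Trajectory` is a uniformly sampled position trace (nominally
30 Hz) in arena coordinates (cm).  Running speed is derived from
Savitzky-Golay smoothed positions by central differences; the same speed
estimate feeds the >10 cm/s movement gate used throughout the analysis so
that every module filters identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["Trajectory", "SpikeTrain", "smooth_positions", "compute_speed"]

#: Smoothing window applied to raw position samples, seconds.
SG_WINDOW_S = 0.166
#: Polynomial order requested for the Savitzky-Golay filter; capped at
#: window-length - 1 when the window is too short to support it.
SG_ORDER = 5


def _window_samples(window_s: float, rate_hz: float) -> int:
    n = max(3, int(round(window_s * rate_hz)))
    return n if n % 2 == 1 else n + 1


def smooth_positions(
    xy: np.ndarray, rate_hz: float, window_s: float = SG_WINDOW_S, order: int = SG_ORDER
) -> np.ndarray:
    """Savitzky-Golay smooth an (n, 2) position array along time."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        return xy.copy()
    win = min(_window_samples(window_s, rate_hz), len(xy) - (1 - len(xy) % 2))
    win = max(win, 3)
    ord_ = min(order, win - 1)
    return savgol_filter(xy, win, ord_, axis=0)


def compute_speed(
    xy: np.ndarray, rate_hz: float, window_s: float = SG_WINDOW_S, order: int = SG_ORDER
) -> np.ndarray:
    """Running speed (cm/s) by central differences on smoothed positions."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return np.zeros(len(xy))
    sm = smooth_positions(xy, rate_hz, window_s, order)
    vel = np.gradient(sm, axis=0) * rate_hz
    return np.hypot(vel[:, 0], vel[:, 1])


@dataclass
class Trajectory:
    """Uniformly sampled position trace.

    ``speed_cm_s`` is computed lazily from the full trace and preserved by
    :meth:`subset` so that time-sliced trajectories keep the speed estimate
    of the uninterrupted recording.
    """

    timestamps: np.ndarray
    xy: np.ndarray
    rate_hz: float
    speed_cm_s: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.timestamps) != len(self.xy):
            raise ValueError("timestamps and xy must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.rate_hz

    @property
    def speed(self) -> np.ndarray:
        if self.speed_cm_s is None:
            self.speed_cm_s = compute_speed(self.xy, self.rate_hz)
        return self.speed_cm_s

    def subset(self, mask: np.ndarray) -> "Trajectory":
        """Boolean-mask subset preserving the precomputed speed."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            timestamps=self.timestamps[mask],
            xy=self.xy[mask],
            speed_cm_s=self.speed[mask] if len(self) else None,
        )


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("spike times must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def between(self, t0: float, t1: float) -> "SpikeTrain":
        keep = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.unit_id, self.times[keep])
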