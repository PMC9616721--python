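"""Occupancy-normalised smoothed firing-rate maps and spatial correlation.

Position samples are binned into 4-cm square bins (half-open intervals,
origin at the arena's south-west corner); only samples with running speed
above 10 cm/s contribute.  Dwell time and spike count grids are smoothed
with a Gaussian kernel (sigma = 2 bins), with unsampled and
out-of-environment bins set to zero before smoothing and no kernel
renormalisation at the borders; the rate map is the ratio of the smoothed
grids.  Grids are indexed ``[ix, iy]`` with x along the arena width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .environments import EnvironmentSpec
from .trajectory import SpikeTrain, Trajectory

__all__ = [
    "Ratemap",
    "compute_ratemap",
    "spatial_correlation",
    "split_session",
    "InsufficientDataError",
]

DEFAULT_BIN_CM = 4.0
DEFAULT_SPEED_MIN = 10.0
DEFAULT_SIGMA_BINS = 2.0
RATE_FLOOR_HZ = 0.01
MIN_VALID_BINS = 6


class InsufficientDataError(ValueError):
    """Raised when no position samples survive the speed filter."""


def grid_shape(env: EnvironmentSpec, bin_cm: float = DEFAULT_BIN_CM) -> tuple[int, int]:
    return (
        int(np.ceil(env.width_cm / bin_cm)),
        int(np.ceil(env.height_cm / bin_cm)),
    )


@dataclass
class Ratemap:
    """Smoothed rate grid plus its dwell/spike/visited layers.

    ``rate`` is NaN at bins with zero smoothed dwell; ``visited`` flags
    bins with nonzero unsmoothed dwell.
    """

    rate: np.ndarray
    dwell_s: np.ndarray
    spike_count: np.ndarray
    visited: np.ndarray
    bin_cm: float
    env: EnvironmentSpec
    sigma_bins: float = DEFAULT_SIGMA_BINS
    unit_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.rate.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.shape
        xs = (np.arange(nx) + 0.5) * self.bin_cm
        ys = (np.arange(ny) + 0.5) * self.bin_cm
        return xs, ys

    @property
    def peak_rate(self) -> float:
        r = self.rate[self.visited]
        return float(np.nanmax(r)) if r.size else 0.0


def bin_positions(
    env: EnvironmentSpec, xy: np.ndarray, bin_cm: float
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Half-open bin indices of positions; positions on the far edge are
    clipped into the last bin."""
    nx, ny = grid_shape(env, bin_cm)
    ix = np.clip((xy[:, 0] // bin_cm).astype(int), 0, nx - 1)
    iy = np.clip((xy[:, 1] // bin_cm).astype(int), 0, ny - 1)
    return ix, iy, (nx, ny)


def _smooth(grid: np.ndarray, sigma_bins: float) -> np.ndarray:
    # zero-fill boundary, kernel truncated at 4 sigma, no renormalisation
    return ndimage.gaussian_filter(grid, sigma=sigma_bins, mode="constant", truncate=4.0)


def compute_ratemap(
    traj: Trajectory,
    spikes: SpikeTrain,
    env: EnvironmentSpec,
    bin_cm: float = DEFAULT_BIN_CM,
    speed_min: float = DEFAULT_SPEED_MIN,
    sigma_bins: float = DEFAULT_SIGMA_BINS,
) -> Ratemap:
    """Build the occupancy-normalised smoothed ratemap of one unit."""
    if len(traj) == 0:
        raise InsufficientDataError("empty trajectory")
    moving = traj.speed > speed_min
    if not np.any(moving):
        raise InsufficientDataError("no samples exceed the speed threshold")

    xy = traj.xy[moving]
    ix, iy, (nx, ny) = bin_positions(env, xy, bin_cm)

    dwell = np.zeros((nx, ny))
    np.add.at(dwell, (ix, iy), 1.0 / traj.rate_hz)

    # pair each spike with its concurrent position sample
    spike_grid = np.zeros((nx, ny))
    if len(spikes):
        idx = np.searchsorted(traj.timestamps, spikes.times, side="right") - 1
        idx = np.clip(idx, 0, len(traj) - 1)
        keep = moving[idx]
        if np.any(keep):
            sx, sy, _ = bin_positions(env, traj.xy[idx[keep]], bin_cm)
            np.add.at(spike_grid, (sx, sy), 1.0)

    sm_dwell = _smooth(dwell, sigma_bins)
    sm_spikes = _smooth(spike_grid, sigma_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(sm_dwell > 0, sm_spikes / np.where(sm_dwell > 0, sm_dwell, 1.0), np.nan)

    return Ratemap(
        rate=rate,
        dwell_s=dwell,
        spike_count=spike_grid,
        visited=dwell > 0,
        bin_cm=bin_cm,
        env=env,
        sigma_bins=sigma_bins,
        unit_id=spikes.unit_id,
    )


def spatial_correlation(
    a: Ratemap | np.ndarray,
    b: Ratemap | np.ndarray,
    visited_a: np.ndarray | None = None,
    visited_b: np.ndarray | None = None,
    rate_floor: float = RATE_FLOOR_HZ,
    min_bins: int = MIN_VALID_BINS,
) -> float:
    """Pearson correlation over jointly visited bins.

    A bin is valid when it is visited in both maps and its rate exceeds
    ``rate_floor`` in at least one of them; NaN is returned when fewer
    than ``min_bins`` valid bins exist.
    """
    ra, va = (a.rate, a.visited) if isinstance(a, Ratemap) else (np.asarray(a), visited_a)
    rb, vb = (b.rate, b.visited) if isinstance(b, Ratemap) else (np.asarray(b), visited_b)
    if ra.shape != rb.shape:
        raise ValueError("ratemap shapes differ")
    va = np.ones(ra.shape, bool) if va is None else va
    vb = np.ones(rb.shape, bool) if vb is None else vb

    valid = va & vb & np.isfinite(ra) & np.isfinite(rb)
    valid &= (ra > rate_floor) | (rb > rate_floor)
    n = int(valid.sum())
    if n < min_bins:
        return float("nan")
    x, y = ra[valid], rb[valid]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(pearsonr(x, y)[0])


def split_session(
    traj: Trajectory,
    spikes: SpikeTrain,
    scheme: str = "odd_even_minutes",
) -> tuple[tuple[Trajectory, SpikeTrain], tuple[Trajectory, SpikeTrain]]:
    """Partition a recording into two disjoint subsets.

    ``odd_even_minutes`` assigns each wall-clock minute (floor(t/60) parity)
    alternately; ``first_last_half`` splits at the temporal midpoint.
    Speed estimates are computed on the full trace before splitting.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t0 = traj.timestamps[0]
    duration = traj.duration_s
    if scheme == "odd_even_minutes":
        if duration < 120.0:
            raise ValueError("odd/even split needs at least 2 minutes")
        parity_pos = (np.floor((traj.timestamps - t0) / 60.0).astype(int)) % 2
        parity_spk = (np.floor((spikes.times - t0) / 60.0).astype(int)) % 2
        mask_a, mask_b = parity_pos == 0, parity_pos == 1
        spk_a, spk_b = parity_spk == 0, parity_spk == 1
    elif scheme == "first_last_half":
        mid = t0 + duration / 2.0
        mask_a, mask_b = traj.timestamps < mid, traj.timestamps >= mid
        spk_a, spk_b = spikes.times < mid, spikes.times >= mid
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return (
        (traj.subset(mask_a), SpikeTrain(spikes.unit_id, spikes.times[spk_a])),
        (traj.subset(mask_b), SpikeTrain(spikes.unit_id, spikes.times[spk_b])),
    )
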