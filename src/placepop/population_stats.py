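"""Wall-distance-banded population statistics.

The arena is segmented into concentric bands by distance of each 4-cm bin
centre to the nearest wall (bands 25 cm wide).  Population homeostasis is
quantified per band as the proportion of co-active cells (ratemap value
>= 1 Hz), the mean population rate, and the Jensen-Shannon divergence
between firing-rate distributions across bands and temporal halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .environments import EnvironmentSpec
from .ratemaps import Ratemap
from .trajectory import SpikeTrain, Trajectory

__all__ = [
    "WallBandPartition",
    "band_partition",
    "band_activity",
    "jensen_shannon",
    "rate_distribution_divergence",
    "total_field_area_by_env",
    "instantaneous_rates",
]

DEFAULT_BAND_CM = 25.0
DEFAULT_ACTIVE_HZ = 1.0


@dataclass
class WallBandPartition:
    """Per-bin wall distance and 25-cm band index."""

    distance_cm: np.ndarray
    band: np.ndarray
    band_cm: float
    bin_cm: float
    env: EnvironmentSpec

    @property
    def n_bands(self) -> int:
        return int(self.band.max()) + 1

    def band_of_positions(self, xy: np.ndarray) -> np.ndarray:
        d = self.env.wall_distance(xy)
        return np.floor(np.clip(d, 0, None) / self.band_cm).astype(int)


def band_partition(
    env: EnvironmentSpec, bin_cm: float = 4.0, band_cm: float = DEFAULT_BAND_CM
) -> WallBandPartition:
    """Distance of each bin centre to the nearest wall, banded."""
    if band_cm <= 0:
        raise ValueError("band_cm must be positive")
    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    xs = (np.arange(nx) + 0.5) * bin_cm
    ys = (np.arange(ny) + 0.5) * bin_cm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dist = np.minimum.reduce(
        [gx, env.width_cm - gx, gy, env.height_cm - gy]
    )
    band = np.floor(np.clip(dist, 0, None) / band_cm).astype(int)
    return WallBandPartition(dist, band, band_cm, bin_cm, env)


def band_activity(
    maps: list[Ratemap],
    part: WallBandPartition,
    active_hz: float = DEFAULT_ACTIVE_HZ,
) -> pd.DataFrame:
    """Per-band proportion of co-active cells and mean population rate.

    Per bin, the co-active proportion is the fraction of units whose
    ratemap value is >= ``active_hz`` and the mean rate averages over all
    units; band values average over the band's visited bins.  Bands with
    no visited bin are absent from the result.
    """
    if not maps:
        raise ValueError("no ratemaps supplied")
    shape = maps[0].shape
    if part.band.shape != shape:
        raise ValueError("partition and ratemaps have mismatched geometry")
    stack = np.stack([m.rate for m in maps])  # units x nx x ny
    visited = np.logical_and.reduce([m.visited for m in maps])
    finite = np.isfinite(stack).all(axis=0)
    ok = visited & finite

    coactive = (np.nan_to_num(stack) >= active_hz).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins are masked out
        mean_rate = np.nanmean(stack, axis=0)

    rows = []
    for b in range(part.n_bands):
        sel = (part.band == b) & ok
        if not sel.any():
            continue
        rows.append(
            {
                "band": b,
                "n_bins": int(sel.sum()),
                "proportion_active": float(coactive[sel].mean()),
                "mean_rate_hz": float(mean_rate[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def instantaneous_rates(
    spikes: list[SpikeTrain],
    traj: Trajectory,
    sigma_s: float = 1.0,
) -> np.ndarray:
    """(units x samples) Gaussian-smoothed rates on the position sample grid."""
    n = len(traj)
    edges = np.concatenate(
        [traj.timestamps - 0.5 / traj.rate_hz, [traj.timestamps[-1] + 0.5 / traj.rate_hz]]
    )
    out = np.empty((len(spikes), n))
    for i, st in enumerate(spikes):
        counts, _ = np.histogram(st.times, bins=edges)
        out[i] = gaussian_filter1d(counts.astype(float), sigma=sigma_s * traj.rate_hz) * traj.rate_hz
    return out


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log; bounded by ln 2)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share support")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        return float("nan")
    p, q = p / ps, q / qs
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def rate_distribution_divergence(
    traj: Trajectory,
    spikes: list[SpikeTrain],
    part: WallBandPartition,
    sigma_s: float = 1.0,
    active_hz: float = DEFAULT_ACTIVE_HZ,
    speed_min: float = 10.0,
    hist_bin_hz: float = 0.5,
) -> pd.DataFrame:
    """JSD between firing-rate distributions across bands and halves.

    Instantaneous rates (1-s-sigma Gaussian smoothing of 30-Hz binned
    spikes) are pooled over cells and samples; only rates >= ``active_hz``
    during movement are kept.  Samples are assigned to wall-distance bands
    by animal position and split into temporal halves; the matrix of
    pairwise divergences over (band, half) distributions is returned in
    long form with columns band_a/half_a/band_b/half_b/jsd.
    """
    if traj.duration_s < 120:
        raise ValueError("recording must be at least 2 minutes")
    rates = instantaneous_rates(spikes, traj, sigma_s)
    moving = traj.speed > speed_min
    band = part.band_of_positions(traj.xy)
    half = (traj.timestamps >= traj.timestamps[0] + traj.duration_s / 2).astype(int)

    groups: dict[tuple[int, int], np.ndarray] = {}
    for b in range(part.n_bands):
        for h in (0, 1):
            sel = moving & (band == b) & (half == h)
            if not sel.any():
                continue
            vals = rates[:, sel]
            vals = vals[vals >= active_hz]
            if vals.size:
                groups[(b, h)] = vals

    if not groups:
        return pd.DataFrame(columns=["band_a", "half_a", "band_b", "half_b", "jsd"])
    pooled = np.concatenate(list(groups.values()))
    top = np.quantile(pooled, 0.999)
    edges = np.arange(active_hz, max(top, active_hz + hist_bin_hz) + hist_bin_hz, hist_bin_hz)
    hists = {k: np.histogram(v, bins=edges)[0].astype(float) for k, v in groups.items()}

    keys = sorted(hists)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            rows.append(
                {
                    "band_a": ka[0],
                    "half_a": ka[1],
                    "band_b": kb[0],
                    "half_b": kb[1],
                    "jsd": jensen_shannon(hists[ka], hists[kb]),
                }
            )
    return pd.DataFrame(rows)


def total_field_area_by_env(
    fields_by_env: dict[str, list],
    areas_m2: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-environment proportion of the total field area.

    Returns columns env/total_area_cm2/proportion, plus proportion_per_m2
    when environment areas are supplied.
    """
    totals = {
        env: float(sum(f.area_cm2 for f in fl)) for env, fl in fields_by_env.items()
    }
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no fields supplied")
    rows = []
    for env, tot in totals.items():
        row = {"env": env, "total_area_cm2": tot, "proportion": tot / grand}
        if areas_m2 is not None:
            row["proportion_per_m2"] = row["proportion"] / areas_m2[env]
        rows.append(row)
    return pd.DataFrame(rows)
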