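"""Poisson-likelihood decoding of position and environment.

Population spike counts K = (k_1..k_N) in a temporal window are compared
against the units' spatial ratemaps under independent-Poisson statistics
with a flat prior over visited bins:

    P(K | x) prod_i  lam_i(x)^{k_i} e^{-lam_i(x)} / k_i!

with lam_i(x) the unit's expected count (ratemap rate times window
duration).  The decoded position is the centre of the maximum-posterior
bin; decoding an environment takes the argmax over the concatenated bins
of all environments.  Ratemaps are cross-validated by excluding a window
(default 3 minutes) surrounding the decoded time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .environments import EnvironmentSpec
from .ratemaps import Ratemap, _smooth, bin_positions, grid_shape
from .trajectory import SpikeTrain, Trajectory

__all__ = [
    "ActivityWindow",
    "PosteriorMap",
    "decode_posterior",
    "decode_position",
    "decode_environment",
    "crossvalidated_maps",
    "count_windows",
    "decode_session",
]

#: Rate floor (Hz) applied to expected rates so that log lam is finite.
RATE_FLOOR_HZ = 0.01
DEFAULT_WINDOW_S = 1.0
DEFAULT_EXCLUSION_S = 180.0


@dataclass
class ActivityWindow:
    """Population spike counts in one temporal window."""

    start_s: float
    duration_s: float
    counts: np.ndarray  # per unit, non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


@dataclass
class PosteriorMap:
    """Posterior probability over visited bin centres (possibly multi-env)."""

    prob: np.ndarray  # per included bin, sums to 1
    centers: np.ndarray  # (n, 2) bin centres, cm
    env_ids: np.ndarray  # per-bin environment label


def _flatten_maps(
    maps: list[Ratemap],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack unit rates over the jointly visited bins of one environment."""
    visited = maps[0].visited
    for m in maps[1:]:
        if m.shape != maps[0].shape:
            raise ValueError("ratemaps must share geometry within an environment")
        visited = visited & m.visited
    idx = np.argwhere(visited)
    rates = np.stack([np.nan_to_num(m.rate, nan=0.0)[visited] for m in maps])
    bin_cm = maps[0].bin_cm
    centers = (idx + 0.5) * bin_cm
    env_ids = np.full(len(idx), maps[0].env.env_id, dtype=object)
    return rates, centers, env_ids


def _log_likelihood(
    counts: np.ndarray, rates: np.ndarray, duration_s: float
) -> np.ndarray:
    """Per-bin Poisson log likelihood; ``rates`` is (units x bins)."""
    lam = np.maximum(rates, RATE_FLOOR_HZ) * duration_s
    k = np.asarray(counts, dtype=float)[:, None]
    return np.sum(k * np.log(lam) - lam - gammaln(k + 1.0), axis=0)


def decode_posterior(
    window: ActivityWindow, maps: list[Ratemap]
) -> PosteriorMap:
    """Posterior over the visited bins of one environment's maps."""
    if len(maps) != len(window.counts):
        raise ValueError("one ratemap per unit is required")
    rates, centers, env_ids = _flatten_maps(maps)
    ll = _log_likelihood(window.counts, rates, window.duration_s)
    prob = np.exp(ll - logsumexp(ll))
    prob = prob / prob.sum()
    return PosteriorMap(prob, centers, env_ids)


def decode_position(post: PosteriorMap) -> np.ndarray:
    """Centre of the maximum-probability bin (lowest index wins ties)."""
    if len(post.prob) == 0:
        raise ValueError("empty posterior")
    return post.centers[int(np.argmax(post.prob))]


def decode_environment(
    window: ActivityWindow, maps_by_env: dict[str, list[Ratemap]]
) -> tuple[str, PosteriorMap]:
    """Environment owning the globally most probable bin.

    The posterior is normalised over the union of visited bins across all
    environments.
    """
    lls, centers, env_ids = [], [], []
    for env_id in sorted(maps_by_env):
        maps = maps_by_env[env_id]
        rates, c, e = _flatten_maps(maps)
        lls.append(_log_likelihood(window.counts, rates, window.duration_s))
        centers.append(c)
        env_ids.append(e)
    ll = np.concatenate(lls)
    prob = np.exp(ll - logsumexp(ll))
    prob /= prob.sum()
    post = PosteriorMap(prob, np.concatenate(centers), np.concatenate(env_ids))
    winner = post.env_ids[int(np.argmax(post.prob))]
    return str(winner), post


def count_windows(
    traj: Trajectory,
    spikes: list[SpikeTrain],
    window_s: float = DEFAULT_WINDOW_S,
    speed_min: float = 10.0,
    min_moving_fraction: float = 0.5,
) -> list[ActivityWindow]:
    """Non-overlapping consecutive windows restricted to movement.

    A window is kept when at least ``min_moving_fraction`` of its position
    samples exceed the speed threshold, matching the ratemap filter.
    """
    t0 = float(traj.timestamps[0])
    n_win = int(np.floor(traj.duration_s / window_s))
    moving = traj.speed > speed_min
    spike_arr = [st.times for st in spikes]
    out = []
    for w in range(n_win):
        a, b = t0 + w * window_s, t0 + (w + 1) * window_s
        sel = (traj.timestamps >= a) & (traj.timestamps < b)
        if not sel.any() or moving[sel].mean() < min_moving_fraction:
            continue
        counts = np.array(
            [np.searchsorted(t, b) - np.searchsorted(t, a) for t in spike_arr]
        )
        out.append(ActivityWindow(a, window_s, counts))
    return out


def crossvalidated_maps(
    traj: Trajectory,
    spikes: list[SpikeTrain],
    env: EnvironmentSpec,
    window_starts: np.ndarray,
    window_s: float = DEFAULT_WINDOW_S,
    exclusion_s: float = DEFAULT_EXCLUSION_S,
    bin_cm: float = 4.0,
    speed_min: float = 10.0,
    sigma_bins: float = 2.0,
):
    """Yield (start_s, maps) with the surrounding exclusion window removed.

    For each decoded window the per-unit ratemaps are recomputed from the
    speed-filtered session excluding ``exclusion_s`` of data centred on
    the window.  Implemented by subtracting the excluded interval's
    unsmoothed dwell/spike histograms from the full-session histograms and
    re-smoothing, which is exact.
    """
    if exclusion_s > 0 and traj.duration_s <= exclusion_s:
        raise ValueError("recording shorter than the exclusion window")
    moving = traj.speed > speed_min
    xy = traj.xy
    ix, iy, (nx, ny) = bin_positions(env, xy, bin_cm)
    dt = 1.0 / traj.rate_hz

    # full-session unsmoothed histograms
    dwell_full = np.zeros((nx, ny))
    np.add.at(dwell_full, (ix[moving], iy[moving]), dt)
    spike_bins = []
    spike_full = []
    for st in spikes:
        idx = np.clip(np.searchsorted(traj.timestamps, st.times, side="right") - 1, 0, len(traj) - 1)
        ok = moving[idx]
        g = np.zeros((nx, ny))
        np.add.at(g, (ix[idx[ok]], iy[idx[ok]]), 1.0)
        spike_full.append(g)
        spike_bins.append((st.times, idx, ok))

    for start in window_starts:
        mid = start + window_s / 2.0
        a, b = mid - exclusion_s / 2.0, mid + exclusion_s / 2.0
        sel = (traj.timestamps >= a) & (traj.timestamps < b) & moving
        dwell = dwell_full.copy()
        np.add.at(dwell, (ix[sel], iy[sel]), -dt)
        sm_dwell = _smooth(dwell, sigma_bins)
        maps = []
        for (times, idx, ok), g_full in zip(spike_bins, spike_full):
            in_win = (times >= a) & (times < b) & ok
            g = g_full.copy()
            if in_win.any():
                np.add.at(g, (ix[idx[in_win]], iy[idx[in_win]]), -1.0)
            sm_sp = _smooth(g, sigma_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(sm_dwell > 0, sm_sp / np.where(sm_dwell > 0, sm_dwell, 1.0), np.nan)
            maps.append(
                Ratemap(
                    rate=rate,
                    dwell_s=dwell,
                    spike_count=g,
                    visited=dwell > 1e-12,
                    bin_cm=bin_cm,
                    env=env,
                    sigma_bins=sigma_bins,
                )
            )
        yield float(start), maps


def decode_session(
    traj: Trajectory,
    spikes: list[SpikeTrain],
    env: EnvironmentSpec,
    window_s: float = DEFAULT_WINDOW_S,
    exclusion_s: float = DEFAULT_EXCLUSION_S,
    speed_min: float = 10.0,
    other_env_maps: dict[str, list[Ratemap]] | None = None,
):
    """Decode every movement window of a session with cross-validated maps.

    Returns a list of dicts (t, true xy, decoded xy, error_cm, and the
    decoded environment when ``other_env_maps`` supplies the remaining
    environments' full-session maps).
    """
    import pandas as pd

    windows = count_windows(traj, spikes, window_s, speed_min)
    starts = np.array([w.start_s for w in windows])
    rows = []
    gen = crossvalidated_maps(
        traj, spikes, env, starts, window_s, exclusion_s, speed_min=speed_min
    )
    for window, (start, maps) in zip(windows, gen):
        sel = (traj.timestamps >= start) & (traj.timestamps < start + window_s)
        true_xy = traj.xy[sel].mean(axis=0)
        if other_env_maps:
            all_maps = dict(other_env_maps)
            all_maps[env.env_id] = maps
            env_hat, post = decode_environment(window, all_maps)
            own = post.env_ids == env.env_id
            own_prob = post.prob[own]
            xy_hat = post.centers[own][int(np.argmax(own_prob))]
        else:
            env_hat = env.env_id
            post = decode_posterior(window, maps)
            xy_hat = decode_position(post)
        rows.append(
            {
                "t": start,
                "true_x": true_xy[0],
                "true_y": true_xy[1],
                "decoded_x": xy_hat[0],
                "decoded_y": xy_hat[1],
                "decoded_env": env_hat,
                "error_cm": float(np.hypot(*(xy_hat - true_xy))),
            }
        )
    return pd.DataFrame(rows)
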