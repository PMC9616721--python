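"""Population-activity change along 1-cm resampled trajectories.

Positions are Savitzky-Golay smoothed (166 ms window); per-unit firing
rates are computed on 33-ms bins and smoothed with a 166-ms-sigma
Gaussian.  The trajectory is reduced to cumulative path length and the
rate matrix is linearly interpolated at positions 1 cm apart; the
population activity change is the Euclidean distance between consecutive
1-cm population vectors.  Periods slower than 10 cm/s split the path into
independent segments — change is never computed across a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .environments import EnvironmentSpec
from .population_stats import WallBandPartition
from .trajectory import SpikeTrain, Trajectory, smooth_positions

__all__ = [
    "PopulationActivity",
    "resample_along_path",
    "activity_change",
    "directional_band_summary",
    "path_integration_distance",
    "covariate_correlation",
    "change_map",
]

DEFAULT_SG_WINDOW_S = 0.166
DEFAULT_SG_ORDER = 5
DEFAULT_RATE_BIN_S = 0.033
DEFAULT_RATE_SIGMA_S = 0.166
DEFAULT_STEP_CM = 1.0
DEFAULT_SPEED_MIN = 10.0


@dataclass
class PopulationActivity:
    """Population rates at 1-cm path increments.

    ``segment`` labels contiguous movement segments; consecutive samples
    within a segment are exactly ``step_cm`` apart in cumulative path
    length.  ``time_s`` is the interpolated wall-clock time per sample.
    """

    positions: np.ndarray  # (n, 2) cm
    rates: np.ndarray  # (units, n) Hz
    heading_deg: np.ndarray
    speed_cm_s: np.ndarray
    wall_dist_orth_cm: np.ndarray
    wall_dist_par_cm: np.ndarray
    path_cm: np.ndarray
    time_s: np.ndarray
    segment: np.ndarray
    step_cm: float
    env: EnvironmentSpec

    def __len__(self) -> int:
        return self.positions.shape[0]


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _wall_distances_along_motion(
    env: EnvironmentSpec, xy: np.ndarray, heading: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest wall along the motion axis (orthogonal
    walls) and along the perpendicular axis (parallel walls)."""

    def ray_distance(xy: np.ndarray, ang: np.ndarray) -> np.ndarray:
        c, s = np.cos(ang), np.sin(ang)
        out = np.full(len(xy), np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            for comp, lo, hi in ((0, 0.0, env.width_cm), (1, 0.0, env.height_cm)):
                d = c if comp == 0 else s
                p = xy[:, comp]
                t1 = np.where(d > 1e-12, (hi - p) / np.abs(d), np.inf)
                t2 = np.where(d < -1e-12, (p - lo) / np.abs(d), np.inf)
                out = np.minimum.reduce([out, t1, t2])
        return out

    fwd = np.minimum(ray_distance(xy, heading), ray_distance(xy, heading + np.pi))
    side = np.minimum(
        ray_distance(xy, heading + np.pi / 2), ray_distance(xy, heading - np.pi / 2)
    )
    return fwd, side


def _binned_rates(
    spikes: list[SpikeTrain],
    t0: float,
    t1: float,
    rate_bin_s: float,
    rate_sigma_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(times, units x bins) Gaussian-smoothed rates on a uniform grid."""
    edges = np.arange(t0, t1 + rate_bin_s, rate_bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.empty((len(spikes), len(centers)))
    sigma_bins = rate_sigma_s / rate_bin_s
    for i, st in enumerate(spikes):
        counts, _ = np.histogram(st.times, bins=edges)
        rates[i] = gaussian_filter1d(counts.astype(float), sigma=sigma_bins) / rate_bin_s
    return centers, rates


def resample_along_path(
    traj: Trajectory,
    spikes: list[SpikeTrain],
    env: EnvironmentSpec,
    sg_window_s: float = DEFAULT_SG_WINDOW_S,
    sg_order: int = DEFAULT_SG_ORDER,
    rate_bin_s: float = DEFAULT_RATE_BIN_S,
    rate_sigma_s: float = DEFAULT_RATE_SIGMA_S,
    step_cm: float = DEFAULT_STEP_CM,
    speed_min: float = DEFAULT_SPEED_MIN,
) -> PopulationActivity:
    """Interpolate population rates at 1-cm path increments.

    The Savitzky-Golay polynomial order is capped at one below the window
    length in samples when necessary (a 166-ms window at 30 Hz holds five
    samples, which cannot support order 5); a warning is emitted.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    win = max(3, int(round(sg_window_s * traj.rate_hz)))
    win += 1 - win % 2
    if sg_order >= win:
        warnings.warn(
            f"Savitzky-Golay order {sg_order} capped at {win - 1} for a "
            f"{win}-sample window",
            stacklevel=2,
        )
    sm = smooth_positions(traj.xy, traj.rate_hz, sg_window_s, sg_order)
    vel = np.gradient(sm, axis=0) * traj.rate_hz
    speed = np.hypot(vel[:, 0], vel[:, 1])
    moving = speed > speed_min

    t0, t1 = float(traj.timestamps[0]), float(traj.timestamps[-1])
    rate_t, rate_mat = _binned_rates(spikes, t0, t1, rate_bin_s, rate_sigma_s)
    # unit rates at the position sample times
    rates_at_pos = np.empty((len(spikes), len(traj)))
    for i in range(len(spikes)):
        rates_at_pos[i] = np.interp(traj.timestamps, rate_t, rate_mat[i])

    pos_out, rate_out, head_out, speed_out = [], [], [], []
    path_out, time_out, seg_out = [], [], []
    seg_id = 0
    for a, b in _segments(moving):
        if b - a < 3:
            continue
        seg_xy = sm[a:b]
        steps = np.hypot(*np.diff(seg_xy, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        if cum[-1] < 2 * step_cm:
            continue
        targets = np.arange(0.0, cum[-1], step_cm)
        # strictly increasing abscissa for interpolation
        keep = np.concatenate([[True], np.diff(cum) > 0])
        cs, idxs = cum[keep], np.arange(a, b)[keep]
        x = np.interp(targets, cs, seg_xy[keep, 0])
        y = np.interp(targets, cs, seg_xy[keep, 1])
        tt = np.interp(targets, cs, traj.timestamps[idxs])
        sp = np.interp(targets, cs, speed[idxs])
        rr = np.empty((len(spikes), len(targets)))
        for i in range(len(spikes)):
            rr[i] = np.interp(targets, cs, rates_at_pos[i, idxs])
        heading = np.arctan2(np.gradient(y), np.gradient(x))
        pos_out.append(np.column_stack([x, y]))
        rate_out.append(rr)
        head_out.append(np.degrees(heading) % 360.0)
        speed_out.append(sp)
        path_out.append(targets)
        time_out.append(tt)
        seg_out.append(np.full(len(targets), seg_id))
        seg_id += 1

    if not pos_out:
        empty = np.empty(0)
        return PopulationActivity(
            np.empty((0, 2)), np.empty((len(spikes), 0)), empty, empty, empty,
            empty, empty, empty, empty.astype(int), step_cm, env,
        )
    positions = np.vstack(pos_out)
    heading_deg = np.concatenate(head_out)
    orth, par = _wall_distances_along_motion(
        env, np.clip(positions, [0, 0], [env.width_cm, env.height_cm]),
        np.radians(heading_deg),
    )
    return PopulationActivity(
        positions=positions,
        rates=np.hstack(rate_out),
        heading_deg=heading_deg,
        speed_cm_s=np.concatenate(speed_out),
        wall_dist_orth_cm=orth,
        wall_dist_par_cm=par,
        path_cm=np.concatenate(path_out),
        time_s=np.concatenate(time_out),
        segment=np.concatenate(seg_out).astype(int),
        step_cm=step_cm,
        env=env,
    )


def resample_grid_along_path(
    spg,
    traj: Trajectory,
    sg_window_s: float = DEFAULT_SG_WINDOW_S,
    sg_order: int = DEFAULT_SG_ORDER,
    step_cm: float = DEFAULT_STEP_CM,
    speed_min: float = DEFAULT_SPEED_MIN,
) -> PopulationActivity:
    """Population activity of an analytic field grid along a trajectory.

    Identical path geometry to :func:`resample_along_path`, but the rate
    matrix is the grid population's noise-free rates evaluated at the
    1-cm path samples (the simulation analogue of recorded activity).
    """
    pa = resample_along_path(
        traj, [], spg.env, sg_window_s, sg_order, step_cm=step_cm, speed_min=speed_min
    )
    clipped = np.clip(
        pa.positions, [0.0, 0.0], [spg.env.width_cm, spg.env.height_cm]
    )
    pa.rates = spg.vectors_at(clipped)
    return pa


def activity_change(pa: PopulationActivity) -> np.ndarray:
    """Euclidean change of the population vector per 1-cm step.

    The value at sample s is ||r(s+1) - r(s)||_2; NaN at the last sample
    of each segment (no within-segment successor).
    """
    n = len(pa)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    diffs = np.linalg.norm(np.diff(pa.rates, axis=1), axis=0)
    same_seg = pa.segment[1:] == pa.segment[:-1]
    out[:-1] = np.where(same_seg, diffs, np.nan)
    return out


def activity_table(
    pa: PopulationActivity,
    change: np.ndarray | None = None,
    wall_margin_cm: float = 12.0,
) -> pd.DataFrame:
    """Per-sample series table ready for delimited-text export."""
    df = pd.DataFrame(
        {
            "sample": np.arange(len(pa)),
            "segment": pa.segment,
            "path_cm": pa.path_cm,
            "x_cm": pa.positions[:, 0],
            "y_cm": pa.positions[:, 1],
            "t_s": pa.time_s,
            "heading_deg": pa.heading_deg,
            "speed_cm_s": pa.speed_cm_s,
            "wall_dist_orth_cm": pa.wall_dist_orth_cm,
            "wall_dist_par_cm": pa.wall_dist_par_cm,
        }
    )
    if change is not None:
        df["change"] = change
    if len(pa):
        df["path_integration_cm"] = path_integration_distance(
            pa, wall_margin_cm=wall_margin_cm
        )
    return df


def heading_sector(heading_deg: np.ndarray, half_width_deg: float = 45.0) -> np.ndarray:
    """Cardinal sector (0=E, 1=N, 2=W, 3=S) of each heading."""
    return (np.round(np.asarray(heading_deg) / 90.0).astype(int)) % 4


def directional_band_summary(
    pa: PopulationActivity,
    change: np.ndarray,
    part: WallBandPartition,
    sector_half_width_deg: float = 45.0,
) -> pd.DataFrame:
    """Mean change per (wall-distance band, motion class).

    Motion is classed ``orthogonal`` when the heading is within the sector
    facing (or backing) the nearest wall's normal, ``parallel`` otherwise.
    Sectors are +/-45 degrees around the cardinal axes by default.
    """
    xy = np.clip(pa.positions, [0, 0], [part.env.width_cm, part.env.height_cm])
    band = part.band_of_positions(xy)
    dx = np.minimum(xy[:, 0], part.env.width_cm - xy[:, 0])
    dy = np.minimum(xy[:, 1], part.env.height_cm - xy[:, 1])
    wall_axis = (dy < dx).astype(int)  # 0: nearest wall normal along x
    sector = heading_sector(pa.heading_deg, sector_half_width_deg)
    motion_axis = (sector % 2).astype(int)  # 0: E/W motion, 1: N/S motion
    orth = motion_axis == wall_axis

    ok = np.isfinite(change)
    rows = []
    for b in range(part.n_bands):
        for label, sel_cls in (("orthogonal", orth), ("parallel", ~orth)):
            sel = ok & sel_cls & (band == b)
            if not sel.any():
                continue
            rows.append(
                {
                    "band": b,
                    "motion": label,
                    "n": int(sel.sum()),
                    "mean_change": float(change[sel].mean()),
                }
            )
    return pd.DataFrame(rows)


def change_map(
    pa: PopulationActivity,
    values: np.ndarray,
    bin_cm: float = 4.0,
) -> np.ndarray:
    """Unsmoothed spatial mean map of a per-sample series (4-cm bins)."""
    env = pa.env
    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    ok = np.isfinite(values)
    xy = np.clip(pa.positions[ok], [0, 0], [env.width_cm - 1e-9, env.height_cm - 1e-9])
    ix = (xy[:, 0] // bin_cm).astype(int)
    iy = (xy[:, 1] // bin_cm).astype(int)
    np.add.at(total, (ix, iy), values[ok])
    np.add.at(count, (ix, iy), 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def path_integration_distance(
    traj_or_pa: Trajectory | PopulationActivity,
    env: EnvironmentSpec | None = None,
    wall_margin_cm: float = 12.0,
) -> np.ndarray:
    """Cumulative distance travelled since last wall contact.

    Contact is the animal being within ``wall_margin_cm`` of any wall; the
    counter is zero at contact samples and accumulates step lengths
    otherwise (per segment for resampled activity).
    """
    if wall_margin_cm <= 0:
        raise ValueError("wall margin must be positive")
    if isinstance(traj_or_pa, PopulationActivity):
        xy = traj_or_pa.positions
        env = traj_or_pa.env
        seg = traj_or_pa.segment
    else:
        xy = traj_or_pa.xy
        if env is None:
            raise ValueError("env is required for a raw trajectory")
        seg = np.zeros(len(xy), dtype=int)
    d = env.wall_distance(xy)
    contact = d <= wall_margin_cm
    steps = np.concatenate([[0.0], np.hypot(*np.diff(xy, axis=0).T)])
    out = np.empty(len(xy))
    acc = 0.0
    for i in range(len(xy)):
        if i > 0 and seg[i] != seg[i - 1]:
            acc = 0.0
        elif i > 0:
            acc += steps[i]
        if contact[i]:
            acc = 0.0
        out[i] = acc
    return out


def covariate_correlation(
    y: np.ndarray, x: np.ndarray, covariates: list[np.ndarray] | None = None
) -> tuple[float, float]:
    """(Pearson r, partial r) of y against x given covariates.

    The partial correlation is the correlation of the least-squares
    residuals of y and x on the covariates (with intercept).  NaN pairs
    are dropped; constant series raise.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in (covariates or [])]
    if len(y) != len(x) or any(len(c) != len(y) for c in covs):
        raise ValueError("series must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    for c in covs:
        ok &= np.isfinite(c)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete samples")
    y, x = y[ok], x[ok]
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant series: correlation undefined")
    r = float(np.corrcoef(y, x)[0, 1])
    if not covs:
        return r, r
    design = np.column_stack([np.ones(len(y))] + [c[ok] for c in covs])
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    if np.ptp(ry) == 0 or np.ptp(rx) == 0:
        raise ValueError("residuals constant: partial correlation undefined")
    return r, float(np.corrcoef(ry, rx)[0, 1])
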