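"""Synthetic foraging sessions with known ground truth.

Emulates the statistical structure the analysis assumes: correlated
random-foraging trajectories in rectangular arenas, place-cell populations
whose per-cell field counts follow a gamma-Poisson law (per-cell propensity
tau ~ Gamma(alpha, theta * A), field count ~ Poisson(tau)), field-centre
density and orthogonal field width optionally varying with wall distance,
and inhomogeneous-Poisson spiking from summed Gaussian fields.

The defaults mirror the emulated recording protocol: 30 Hz position sampling,
recording duration scaling with arena area (15 min per 1.09 m^2 arena),
and foraging speeds mostly above the 10 cm/s movement gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .environments import EnvironmentSpec
from .trajectory import SpikeTrain, Trajectory

__all__ = [
    "GaussianField",
    "SimCell",
    "generate_trajectory",
    "generate_population",
    "generate_spikes",
    "cell_intensity",
    "session_duration_s",
]

#: Default out-of-field baseline rate, Hz; keeps out-of-field bins from
#: being identically zero, as in noisy recordings.
DEFAULT_BASELINE_HZ = 0.05
#: Soft-core offset (cm) for the 1/(d + d0)^2 wall-distance density law.
DENSITY_D0_CM = 5.0
#: Cap on the wall-distance-scaled orthogonal sigma, cm.
SIGMA_MAX_CM = 40.0


@dataclass(frozen=True)
class GaussianField:
    """One Gaussian firing field; the centre may lie outside the walls."""

    center_xy: tuple[float, float]
    sigma_x_cm: float
    sigma_y_cm: float
    amplitude_hz: float

    def __post_init__(self) -> None:
        if self.sigma_x_cm <= 0 or self.sigma_y_cm <= 0:
            raise ValueError("field sigmas must be positive")
        if self.amplitude_hz < 0:
            raise ValueError("field amplitude must be non-negative")


@dataclass
class SimCell:
    """A simulated place cell: propensity, fields and baseline rate."""

    unit_id: str
    tau: float
    fields: list[GaussianField] = dc_field(default_factory=list)
    baseline_hz: float = DEFAULT_BASELINE_HZ


def session_duration_s(env: EnvironmentSpec, minutes_per_m2: float = 15.0 / 1.09375) -> float:
    """Recording duration scaling linearly with arena area (15 min at 1.09 m^2)."""
    return 60.0 * minutes_per_m2 * env.area_m2


def generate_trajectory(
    env: EnvironmentSpec,
    duration_s: float,
    rate_hz: float = 30.0,
    speed_mean: float = 17.5,
    speed_sd: float = 6.0,
    heading_sigma: float = 1.6,
    speed_tau_s: float = 1.5,
    seed: int = 0,
) -> Trajectory:
    """Correlated random-foraging path with elastic wall reflection.

    Heading follows a Brownian rotation (``heading_sigma`` rad per sqrt(s));
    speed follows an Ornstein-Uhlenbeck process around ``speed_mean`` with
    stationary spread ``speed_sd``.  Walls reflect elastically.  With the
    protocol's duration-area scaling this covers >= 95% of 4-cm bins.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    if speed_mean <= 0:
        raise ValueError("speed_mean must be positive")

    n = int(round(duration_s * rate_hz))
    if n == 0:
        return Trajectory(np.empty(0), np.empty((0, 2)), rate_hz)

    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    w, h = env.width_cm, env.height_cm

    # OU speed: discrete AR(1) with the requested stationary sd
    phi = np.exp(-dt / speed_tau_s)
    eps_sd = speed_sd * np.sqrt(1.0 - phi**2)

    xy = np.empty((n, 2))
    pos = np.array([rng.uniform(0.1 * w, 0.9 * w), rng.uniform(0.1 * h, 0.9 * h)])
    heading = rng.uniform(0, 2 * np.pi)
    speed = max(0.0, rng.normal(speed_mean, speed_sd))

    turns = rng.normal(0.0, heading_sigma * np.sqrt(dt), size=n)
    speed_eps = rng.normal(0.0, eps_sd, size=n)

    for i in range(n):
        heading += turns[i]
        speed = speed_mean + phi * (speed - speed_mean) + speed_eps[i]
        speed = max(0.0, speed)
        step = speed * dt
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        # elastic reflection on each axis
        if pos[0] < 0:
            pos[0] = -pos[0]
            heading = np.pi - heading
        elif pos[0] > w:
            pos[0] = 2 * w - pos[0]
            heading = np.pi - heading
        if pos[1] < 0:
            pos[1] = -pos[1]
            heading = -heading
        elif pos[1] > h:
            pos[1] = 2 * h - pos[1]
            heading = -heading
        pos[0] = min(max(pos[0], 0.0), w)
        pos[1] = min(max(pos[1], 0.0), h)
        xy[i] = pos

    timestamps = np.arange(n) * dt
    return Trajectory(timestamps, xy, rate_hz)


def _wall_distance_signed(env: EnvironmentSpec, xy: np.ndarray) -> np.ndarray:
    """Distance to the nearest wall; negative outside the arena."""
    xy = np.atleast_2d(xy)
    return np.minimum.reduce(
        [xy[:, 0], env.width_cm - xy[:, 0], xy[:, 1], env.height_cm - xy[:, 1]]
    )


def _sample_centers(
    env: EnvironmentSpec,
    n: int,
    placement_law: str,
    sigma0: float,
    rng: np.random.Generator,
    d0: float = DENSITY_D0_CM,
) -> np.ndarray:
    """Sample field centres; may fall up to one sigma outside the walls."""
    margin = sigma0
    lo = np.array([-margin, -margin])
    hi = np.array([env.width_cm + margin, env.height_cm + margin])
    if placement_law == "uniform":
        return rng.uniform(lo, hi, size=(n, 2))
    if placement_law == "inverse_square":
        # rejection sampling against density ~ 1/(d + d0)^2, d clipped at 0
        out = np.empty((n, 2))
        got = 0
        wmax = 1.0 / d0**2
        while got < n:
            m = max(4 * (n - got), 64)
            cand = rng.uniform(lo, hi, size=(m, 2))
            d = np.clip(_wall_distance_signed(env, cand), 0.0, None)
            w = 1.0 / (d + d0) ** 2
            keep = rng.uniform(0, wmax, size=m) < w
            take = min(int(keep.sum()), n - got)
            out[got : got + take] = cand[keep][:take]
            got += take
        return out
    raise ValueError(f"unknown placement_law {placement_law!r}")


def _orthogonal_axis(env: EnvironmentSpec, xy: np.ndarray) -> np.ndarray:
    """0 where the nearest wall is E/W (normal along x), 1 where N/S."""
    xy = np.atleast_2d(xy)
    dx = np.minimum(xy[:, 0], env.width_cm - xy[:, 0])
    dy = np.minimum(xy[:, 1], env.height_cm - xy[:, 1])
    return (dy < dx).astype(int)


def generate_population(
    env: EnvironmentSpec,
    n_cells: int,
    alpha: float = 1.0,
    theta: float = 0.28,
    placement_law: str = "uniform",
    width_law: str = "fixed",
    sigma0_cm: float = 10.0,
    width_d0_cm: float = 25.0,
    sigma_max_cm: float = SIGMA_MAX_CM,
    amplitude_hz: float = 6.0,
    amplitude_sigma: float = 0.4,
    baseline_hz: float = DEFAULT_BASELINE_HZ,
    seed: int = 0,
) -> list[SimCell]:
    """Draw a place-cell population with gamma-Poisson field counts.

    Per-cell propensity tau ~ Gamma(alpha, scale=theta * A) with A the arena
    area in m^2; the field count of each cell is Poisson(tau).  Centres are
    placed by ``placement_law`` ("uniform" or "inverse_square", the latter
    concentrating centres near walls); with ``width_law="square_scaling"``
    the sigma orthogonal to the nearest wall grows with squared wall
    distance, capped at ``sigma_max_cm``.  Amplitudes are log-normal around
    ``amplitude_hz``.
    """
    if alpha <= 0 or theta <= 0:
        raise ValueError("alpha and theta must be positive")
    if width_law not in ("fixed", "square_scaling"):
        raise ValueError(f"unknown width_law {width_law!r}")

    rng = np.random.default_rng(seed)
    area = env.area_m2
    taus = rng.gamma(shape=alpha, scale=theta * area, size=n_cells)
    counts = rng.poisson(taus)

    cells: list[SimCell] = []
    for i in range(n_cells):
        k = int(counts[i])
        fields: list[GaussianField] = []
        if k > 0:
            centers = _sample_centers(env, k, placement_law, sigma0_cm, rng)
            amps = amplitude_hz * rng.lognormal(0.0, amplitude_sigma, size=k)
            d = np.clip(_wall_distance_signed(env, centers), 0.0, None)
            axis = _orthogonal_axis(env, centers)
            for j in range(k):
                if width_law == "fixed":
                    sx = sy = sigma0_cm
                else:
                    s_orth = min(
                        sigma0_cm * ((d[j] + width_d0_cm) / width_d0_cm) ** 2,
                        sigma_max_cm,
                    )
                    if axis[j] == 0:  # nearest wall normal along x
                        sx, sy = s_orth, sigma0_cm
                    else:
                        sx, sy = sigma0_cm, s_orth
                fields.append(
                    GaussianField(
                        (float(centers[j, 0]), float(centers[j, 1])),
                        float(sx),
                        float(sy),
                        float(amps[j]),
                    )
                )
        cells.append(SimCell(unit_id=f"cell{i:04d}", tau=float(taus[i]), fields=fields,
                             baseline_hz=baseline_hz))
    return cells


def cell_intensity(cell: SimCell, xy: np.ndarray) -> np.ndarray:
    """Firing intensity (Hz) of a cell at positions ``xy`` (n, 2)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    lam = np.full(len(xy), float(cell.baseline_hz))
    for f in cell.fields:
        dx = (xy[:, 0] - f.center_xy[0]) / f.sigma_x_cm
        dy = (xy[:, 1] - f.center_xy[1]) / f.sigma_y_cm
        lam += f.amplitude_hz * np.exp(-0.5 * (dx**2 + dy**2))
    return lam


def generate_spikes(
    cells: list[SimCell],
    traj: Trajectory,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains by thinning.

    For each cell, candidate events are drawn from a homogeneous Poisson
    process at the cell's intensity upper bound (baseline plus the sum of
    field amplitudes) and accepted with probability intensity/bound, with
    the intensity evaluated at the animal's interpolated position.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must be non-empty")
    t0, t1 = float(traj.timestamps[0]), float(traj.timestamps[-1])
    duration = t1 - t0
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    trains: list[SpikeTrain] = []
    for cell, ss in zip(cells, seeds):
        rng = np.random.default_rng(ss)
        lam_max = cell.baseline_hz + sum(f.amplitude_hz for f in cell.fields)
        if lam_max <= 0 or duration <= 0:
            trains.append(SpikeTrain(cell.unit_id, np.empty(0)))
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(t0, t1, size=n_cand))
        x = np.interp(cand, traj.timestamps, traj.xy[:, 0])
        y = np.interp(cand, traj.timestamps, traj.xy[:, 1])
        lam = cell_intensity(cell, np.column_stack([x, y]))
        accept = rng.uniform(0, lam_max, size=n_cand) < lam
        trains.append(SpikeTrain(cell.unit_id, cand[accept]))
    return trains
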