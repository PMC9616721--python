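"""Analytic Gaussian-field population grids.

Two reference constructions used as oracles for the population-level
statistics:

* a uniform lattice of equal-sized Gaussian fields extending beyond the
  walls (so that some centres are inaccessible and their measurable
  fields appear cut off), whose summed activity and population-vector
  rate of change are constant everywhere; and
* a boundary-scaled population in which field-centre density falls off
  as 1/(x + d0)^2 with wall distance x while the orthogonal field width
  grows as (x + d0)^2, so total activity stays flat but the population
  vector turns over fastest near walls for orthogonal motion.

Fields are axis-aligned Gaussians evaluated in closed form; populations
convert to single-field simulated cells for spiking via
:func:`placepop.synthetic.generate_spikes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .environments import EnvironmentSpec
from .synthetic import GaussianField, SimCell

__all__ = [
    "SimPopulationGrid",
    "build_uniform_population",
    "build_boundary_population",
    "evaluate_population",
]

log = logging.getLogger(__name__)

#: Cap on the wall-distance-scaled orthogonal sigma, cm.
SIGMA_MAX_CM = 40.0


@dataclass
class SimPopulationGrid:
    """Axis-aligned Gaussian field population (one field per cell)."""

    centers: np.ndarray  # (n, 2) cm; may lie beyond the walls
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    amplitudes: np.ndarray
    env: EnvironmentSpec

    @property
    def n_fields(self) -> int:
        return len(self.amplitudes)

    def vectors_at(self, points: np.ndarray) -> np.ndarray:
        """(n_fields, n_points) per-cell rates at the given positions."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = (pts[:, 0][None, :] - self.centers[:, 0][:, None]) / self.sigma_x[:, None]
        dy = (pts[:, 1][None, :] - self.centers[:, 1][:, None]) / self.sigma_y[:, None]
        return self.amplitudes[:, None] * np.exp(-0.5 * (dx**2 + dy**2))

    def summed_rate(self, points: np.ndarray) -> np.ndarray:
        return self.vectors_at(points).sum(axis=0)

    def to_cells(self, baseline_hz: float = 0.0) -> list[SimCell]:
        cells = []
        for i in range(self.n_fields):
            f = GaussianField(
                (float(self.centers[i, 0]), float(self.centers[i, 1])),
                float(self.sigma_x[i]),
                float(self.sigma_y[i]),
                float(self.amplitudes[i]),
            )
            cells.append(SimCell(f"grid{i:05d}", tau=1.0, fields=[f], baseline_hz=baseline_hz))
        return cells


def build_uniform_population(
    env: EnvironmentSpec,
    n_fields: int = 1271,
    sigma_cm: float = 12.0,
    margin_cm: float = 25.0,
    amplitude_hz: float = 5.0,
) -> SimPopulationGrid:
    """Equal Gaussian fields on a regular lattice spanning the arena plus margin.

    The lattice aspect follows the padded arena; when no integer lattice
    matches ``n_fields`` exactly the nearest feasible lattice is used and
    the realised count logged.
    """
    w = env.width_cm + 2 * margin_cm
    h = env.height_cm + 2 * margin_cm
    ny = max(1, int(round(np.sqrt(n_fields * h / w))))
    nx = max(1, int(round(n_fields / ny)))
    if nx * ny != n_fields:
        log.warning("lattice %dx%d yields %d fields (requested %d)", nx, ny, nx * ny, n_fields)
    xs = np.linspace(-margin_cm, env.width_cm + margin_cm, nx)
    ys = np.linspace(-margin_cm, env.height_cm + margin_cm, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    n = len(centers)
    return SimPopulationGrid(
        centers=centers,
        sigma_x=np.full(n, float(sigma_cm)),
        sigma_y=np.full(n, float(sigma_cm)),
        amplitudes=np.full(n, float(amplitude_hz)),
        env=env,
    )


def _arena_grid(env: EnvironmentSpec, bin_cm: float = 4.0) -> np.ndarray:
    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    xs = (np.arange(nx) + 0.5) * bin_cm
    ys = (np.arange(ny) + 0.5) * bin_cm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _sat_distance(d0: float, sigma0: float, sigma_max: float) -> float:
    """Wall distance at which the squared-distance width law hits its cap."""
    return d0 * (np.sqrt(sigma_max / sigma0) - 1.0)


def _axis_sigma(
    coords: np.ndarray, length: float, d0: float, sigma0: float, sigma_max: float
) -> np.ndarray:
    """Width law per axis: sigma0 ((d + d0) / d0)^2 in the distance d to
    the nearer wall along that axis, capped; cut-off centres beyond the
    walls keep the wall-scale width sigma0."""
    d = np.clip(np.minimum(coords, length - coords), 0.0, None)
    return np.minimum(sigma0 * ((d + d0) / d0) ** 2, sigma_max)


def _axis_layout(
    length: float,
    n: int,
    d0: float,
    density: str,
    sigma0: float,
    sigma_max: float,
    flatten_iters: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """1D row coordinates and widths for one axis.

    Rows sit at equal quantiles of the density law — 1/(min(d, d_c) +
    d0)^2 in the wall distance d, saturating at the distance d_c where
    the paired width law caps, so that density and width invert each
    other at every distance — over a domain padded by 2.5 sigma0 beyond
    both walls (cut-off fields).  With ``flatten_iters`` > 0 the density
    is further corrected numerically so the 1D lattice sum of unit
    Gaussians is flat over the arena; amplitudes stay equal, which keeps
    the co-active fraction as flat as the summed rate.
    """
    pad = 2.5 * sigma0
    grid = np.linspace(-pad, length + pad, 2048)
    dist = np.clip(np.minimum(grid, length - grid), 0.0, None)
    if density == "inverse_square":
        uc = _sat_distance(d0, sigma0, sigma_max)
        rho = 1.0 / (np.minimum(dist, uc) + d0) ** 2
    else:
        rho = np.ones_like(grid)
        # uniform control keeps centres inside the arena only
        rho[(grid < 0) | (grid > length)] = 0.0

    eval_pts = np.linspace(0.0, length, 512)
    coords = sigs = None
    for it in range(flatten_iters + 1):
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]) * np.diff(grid))])
        q = (np.arange(n) + 0.5) / n * cdf[-1]
        coords = np.interp(q, cdf, grid)
        sigs = _axis_sigma(coords, length, d0, sigma0, sigma_max)
        if it == flatten_iters:
            break
        g = np.exp(
            -0.5 * ((eval_pts[None, :] - coords[:, None]) / sigs[:, None]) ** 2
        ).sum(axis=0)
        corr = g.mean() / np.interp(np.clip(grid, 0.0, length), eval_pts, g)
        rho = rho * corr
    return coords, sigs


def build_boundary_population(
    env: EnvironmentSpec,
    d0_cm: float = 55.0,
    sigma0_cm: float = 8.0,
    normalize: bool = True,
    density: str = "inverse_square",
    n_x: int | None = None,
    n_y: int | None = None,
    sigma_max_cm: float = SIGMA_MAX_CM,
    amplitude_hz: float = 4.0,
    n_normalize_iter: int = 5,
) -> SimPopulationGrid:
    """Boundary-scaled population: dense narrow fields near walls.

    The density and width laws act separably per axis, mirroring the
    observation that field width in a given axis follows the nearest wall
    distance along that axis: centre x-coordinates follow density
    1/(dx + d0)^2 in the distance dx to the nearer east/west wall (y
    likewise), and a field's sigma_x grows as sigma0 ((dx + d0) / d0)^2
    capped at ``sigma_max_cm`` (sigma_y likewise in dy).  Because the
    per-axis density is the inverse of the per-axis width (both saturate
    together), the summed rate is close to constant by construction, and
    the density extends a little beyond the walls (cut-off fields) so
    coverage holds at the boundary.  With ``normalize`` the per-axis row
    density is additionally corrected numerically until the lattice sum
    is flat over the arena to within ~2%; all amplitudes stay equal, so
    the proportion of co-active fields is as flat as the summed rate.
    With ``density="uniform"`` the centres are equally spaced while
    widths still grow — a non-homeostatic control whose summed rate and
    mean rate rise toward the centre.
    """
    if d0_cm <= 0:
        raise ValueError("d0_cm must be positive")
    if density not in ("inverse_square", "uniform"):
        raise ValueError(f"unknown density {density!r}")
    if n_x is None:
        n_x = max(8, int(round(env.width_cm / 9.0)))
    if n_y is None:
        n_y = max(8, int(round(env.height_cm / 9.0)))

    iters = n_normalize_iter if normalize else 0
    xs, sxs = _axis_layout(env.width_cm, n_x, d0_cm, density, sigma0_cm, sigma_max_cm, iters)
    ys, sys_ = _axis_layout(env.height_cm, n_y, d0_cm, density, sigma0_cm, sigma_max_cm, iters)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sgx, sgy = np.meshgrid(sxs, sys_, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    return SimPopulationGrid(
        centers=centers,
        sigma_x=sgx.ravel().copy(),
        sigma_y=sgy.ravel().copy(),
        amplitudes=np.full(len(centers), float(amplitude_hz)),
        env=env,
    )


def evaluate_population(
    spg: SimPopulationGrid,
    points: np.ndarray,
    directions: np.ndarray,
    step_cm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(summed rate, per-cell vectors, directional change) at given points.

    ``directions`` are unit vectors; the change at a point p is
    ``||v(p + step * d) - v(p)||_2`` over the cell dimension.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.shape != pts.shape:
        dirs = np.broadcast_to(dirs, pts.shape)
    v0 = spg.vectors_at(pts)
    v1 = spg.vectors_at(pts + step_cm * dirs)
    change = np.linalg.norm(v1 - v0, axis=0)
    return v0.sum(axis=0), v0, change
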