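"""Ray-cast reconstruction of the animal's visual scene.

A three-camera rig (5 cm above the floor, pitched 35 degrees above the
horizontal, yaw offsets -100/0/+100 degrees, each 100-degree field of
view at 64 x 64 pixels, 300 degrees total coverage) renders the arena as
a flat-lit box: a grey floor, darker walls 60 cm high with high-contrast
cue panels, and black surround above the walls.  One primary ray is cast
per pixel; the nearest surface's luminance is returned with no lighting
model.  The per-sample visual-change statistic is the per-pixel absolute
difference of consecutive frames, z-scored per pixel across the session
and averaged over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environments import EnvironmentSpec, WallCue

__all__ = [
    "CameraRig",
    "SceneModel",
    "render_pose",
    "render_sequence",
    "visual_change_series",
]

FLOOR_LUM = 0.15
WALL_LUM = 0.05
SURROUND_LUM = 0.0


@dataclass(frozen=True)
class CameraRig:
    """Three-camera greyscale rig covering 300 degrees."""

    height_cm: float = 5.0
    pitch_deg: float = 35.0
    yaw_offsets_deg: tuple[float, ...] = (-100.0, 0.0, 100.0)
    fov_deg: float = 100.0
    n_pixels: int = 64


@dataclass(frozen=True)
class SceneModel:
    """Flat-lit box scene: floor, 60-cm walls, cue panels, black surround."""

    env: EnvironmentSpec
    floor_lum: float = FLOOR_LUM
    wall_lum: float = WALL_LUM
    surround_lum: float = SURROUND_LUM


def _pixel_grid(rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    """Image-plane offsets (u right, v up) for the pixel centres."""
    half = np.tan(np.radians(rig.fov_deg / 2.0))
    step = 2.0 * half / rig.n_pixels
    coords = -half + (np.arange(rig.n_pixels) + 0.5) * step
    # left-to-right columns; first row is the top of the image
    u, v = np.meshgrid(coords, coords[::-1], indexing="xy")
    return u, v


def _cue_luminance(
    cue: WallCue, along: np.ndarray, z: np.ndarray, lum: np.ndarray, hit: np.ndarray
) -> None:
    """Overwrite wall luminance where rays strike the cue panel."""
    in_panel = (
        hit
        & (along >= cue.offset_cm)
        & (along <= cue.offset_cm + cue.width_cm)
        & (z >= cue.bottom_cm)
        & (z <= cue.bottom_cm + cue.height_cm)
    )
    if np.any(in_panel):
        uu = (along[in_panel] - cue.offset_cm) / cue.width_cm
        vv = (z[in_panel] - cue.bottom_cm) / cue.height_cm
        lum[in_panel] = np.clip(cue.pattern(uu, vv), 0.0, 1.0)


def _trace(scene: SceneModel, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Luminance of the nearest surface along each ray (n, 3)."""
    env = scene.env
    ox, oy, oz = origin
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    eps = 1e-12

    # distance to each of the four wall planes (inf when pointing away)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_w = np.where(dx < -eps, (0.0 - ox) / dx, np.inf)
        t_e = np.where(dx > eps, (env.width_cm - ox) / dx, np.inf)
        t_s = np.where(dy < -eps, (0.0 - oy) / dy, np.inf)
        t_n = np.where(dy > eps, (env.height_cm - oy) / dy, np.inf)
        t_floor = np.where(dz < -eps, -oz / dz, np.inf)

    t_walls = np.stack([t_w, t_e, t_s, t_n])
    wall_idx = np.argmin(t_walls, axis=0)
    t_wall = t_walls[wall_idx, np.arange(len(dx))]

    lum = np.full(len(dx), scene.surround_lum)
    floor_first = t_floor < t_wall
    lum[floor_first] = scene.floor_lum

    hit_wall = ~floor_first & np.isfinite(t_wall)
    z_at_wall = oz + t_wall * dz
    on_wall = hit_wall & (z_at_wall <= env.wall_height_cm) & (z_at_wall >= 0)
    lum[on_wall] = scene.wall_lum

    # cue panels override the wall luminance
    x_at = ox + t_wall * dx
    y_at = oy + t_wall * dy
    wall_names = ("W", "E", "S", "N")
    along_coord = (y_at, y_at, x_at, x_at)
    for cue in env.cues:
        w = wall_names.index(cue.wall)
        hit = on_wall & (wall_idx == w)
        _cue_luminance(cue, along_coord[w], z_at_wall, lum, hit)
    return lum


_RIG_CACHE: dict[tuple, np.ndarray] = {}


def _camera_dirs(rig: CameraRig) -> np.ndarray:
    """Unrotated per-camera pixel directions, camera at yaw 0 (n_pix, 3)."""
    key = (rig.fov_deg, rig.n_pixels, rig.pitch_deg)
    if key not in _RIG_CACHE:
        u, v = _pixel_grid(rig)
        p = np.radians(rig.pitch_deg)
        fwd = np.array([np.cos(p), 0.0, np.sin(p)])
        right = np.array([0.0, -1.0, 0.0])
        up = np.cross(right, fwd)
        dirs = (
            fwd[None, :]
            + u.ravel()[:, None] * right[None, :]
            + v.ravel()[:, None] * up[None, :]
        )
        _RIG_CACHE[key] = dirs
    return _RIG_CACHE[key]


def render_pose(
    scene: SceneModel, rig: CameraRig, xy: np.ndarray, heading_deg: float
) -> np.ndarray:
    """Render the three camera frames at one pose -> (3, n, n) in [0, 1]."""
    env = scene.env
    if not env.contains(np.asarray(xy)[None, :], tol_cm=1.0)[0]:
        raise ValueError(f"pose {xy} lies outside the arena")
    x = float(np.clip(xy[0], 0.0, env.width_cm))
    y = float(np.clip(xy[1], 0.0, env.height_cm))
    origin = np.array([x, y, rig.height_cm])
    base = _camera_dirs(rig)
    n = rig.n_pixels
    frames = np.empty((len(rig.yaw_offsets_deg), n, n))
    for ci, off in enumerate(rig.yaw_offsets_deg):
        yaw = np.radians(heading_deg + off)
        c, s = np.cos(yaw), np.sin(yaw)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        dirs = base @ rot.T
        frames[ci] = _trace(scene, origin, dirs).reshape(n, n)
    return frames


def render_sequence(
    scene: SceneModel,
    rig: CameraRig,
    poses: np.ndarray,
    headings_deg: np.ndarray,
) -> np.ndarray:
    """Render a pose sequence -> (samples, 3, n, n); deterministic."""
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    headings = np.atleast_1d(np.asarray(headings_deg, dtype=float))
    if len(poses) != len(headings):
        raise ValueError("poses and headings must have equal length")
    n = rig.n_pixels
    out = np.empty((len(poses), len(rig.yaw_offsets_deg), n, n))
    for i in range(len(poses)):
        out[i] = render_pose(scene, rig, poses[i], float(headings[i]))
    return out


def visual_change_for_path(
    scene: SceneModel,
    rig: CameraRig,
    positions: np.ndarray,
    headings_deg: np.ndarray,
    segment: np.ndarray | None = None,
) -> np.ndarray:
    """Streaming visual-change series for long pose sequences.

    Equivalent to rendering the full stack and calling
    :func:`visual_change_series`, but frames are rendered one at a time
    and only the per-pixel absolute differences (float32) are retained.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    headings = np.asarray(headings_deg, dtype=float)
    n = len(positions)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    if segment is None:
        segment = np.zeros(n, dtype=int)
    npix = len(rig.yaw_offsets_deg) * rig.n_pixels**2
    diffs = np.empty((n - 1, npix), dtype=np.float32)
    keep = np.zeros(n - 1, dtype=bool)
    prev = render_pose(scene, rig, positions[0], headings[0]).ravel()
    for i in range(1, n):
        cur = render_pose(scene, rig, positions[i], headings[i]).ravel()
        if segment[i] == segment[i - 1]:
            diffs[i - 1] = np.abs(cur - prev)
            keep[i - 1] = True
        prev = cur
    d = diffs[keep]
    mu = d.mean(axis=0, dtype=np.float64)
    sd = d.std(axis=0, dtype=np.float64)
    safe = sd > 0
    inv = np.zeros_like(sd)
    inv[safe] = 1.0 / sd[safe]
    offset = float((mu * inv).sum() / npix)
    vals = (d @ inv) / npix - offset
    out[np.where(keep)[0]] = vals
    return out


def visual_change_series(
    frames: np.ndarray, segment: np.ndarray | None = None
) -> np.ndarray:
    """Per-sample visual change from a frame stack aligned to path samples.

    The change at sample s is the mean over pixels of the per-pixel
    z-scored absolute difference between frames s and s+1; NaN at the
    last sample of each segment.  Pixels whose difference never varies
    contribute zero.
    """
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    if segment is None:
        segment = np.zeros(n, dtype=int)
    same = segment[1:] == segment[:-1]
    diffs = np.abs(frames[1:] - frames[:-1])[same]
    if len(diffs) == 0:
        return out
    mu = diffs.mean(axis=0)
    sd = diffs.std(axis=0)
    safe = sd > 0
    z = np.zeros_like(diffs)
    z[:, safe] = (diffs[:, safe] - mu[safe]) / sd[safe]
    vals = z.reshape(len(diffs), -1).mean(axis=1)
    idx = np.where(same)[0]
    out[idx] = vals
    return out
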