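"""Rectangular recording arenas and their wall-mounted visual cues.

The preset arenas are four rectangles of identical proportion (axis ratio
1.40), each doubling the area of the previous one: A (87.5 x 125 cm,
1.09 m^2) through D (350 x 250 cm, 8.75 m^2).  Coordinates are expressed
in centimetres with the origin at the south-west corner; ``x`` runs along
the east-west extent (``width_cm``) and ``y`` along the north-south extent
(``height_cm``).  Walls are 60 cm high; cues are high-contrast panels
mounted on the walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

Wall = Literal["N", "S", "E", "W"]

__all__ = ["WallCue", "EnvironmentSpec", "PRESETS", "preset", "stripes", "checker"]


def stripes(n: int = 6) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Vertical black/white stripe pattern with ``n`` full periods."""

    def pattern(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return (np.floor(np.asarray(u) * 2 * n) % 2).astype(float)

    return pattern


def checker(n: int = 4) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Checkerboard pattern with ``n`` squares along each cue axis."""

    def pattern(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        iu = np.floor(np.asarray(u) * n)
        iv = np.floor(np.asarray(v) * n)
        return ((iu + iv) % 2).astype(float)

    return pattern


@dataclass(frozen=True)
class WallCue:
    """A luminance panel on one wall.

    ``offset_cm`` is the distance from the wall's low-coordinate end to the
    left edge of the panel, measured along the wall; ``pattern(u, v)`` maps
    panel-local coordinates in [0, 1] x [0, 1] to luminance in [0, 1].
    """

    wall: Wall
    offset_cm: float
    width_cm: float
    height_cm: float
    bottom_cm: float = 20.0
    pattern: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(
        default_factory=stripes
    )


@dataclass(frozen=True)
class EnvironmentSpec:
    """Rectangular arena geometry plus wall cues."""

    env_id: str
    width_cm: float
    height_cm: float
    wall_height_cm: float = 60.0
    cues: tuple[WallCue, ...] = ()

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena extents must be positive")
        for cue in self.cues:
            extent = self.wall_extent(cue.wall)
            if cue.offset_cm < 0 or cue.offset_cm + cue.width_cm > extent + 1e-9:
                raise ValueError(
                    f"cue on wall {cue.wall} exceeds the wall extent {extent} cm"
                )

    @property
    def area_m2(self) -> float:
        return self.width_cm * self.height_cm / 1e4

    def wall_extent(self, wall: Wall) -> float:
        return self.width_cm if wall in ("N", "S") else self.height_cm

    def contains(self, xy: np.ndarray, tol_cm: float = 0.0) -> np.ndarray:
        """Boolean mask of positions inside the arena (with tolerance)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= -tol_cm)
            & (xy[:, 0] <= self.width_cm + tol_cm)
            & (xy[:, 1] >= -tol_cm)
            & (xy[:, 1] <= self.height_cm + tol_cm)
        )

    def wall_distance(self, xy: np.ndarray) -> np.ndarray:
        """Distance from each position to the nearest of the four walls."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.minimum.reduce(
            [
                xy[:, 0],
                self.width_cm - xy[:, 0],
                xy[:, 1],
                self.height_cm - xy[:, 1],
            ]
        )


def _preset(env_id: str, width: float, height: float, cues: tuple[WallCue, ...]) -> EnvironmentSpec:
    return EnvironmentSpec(env_id=env_id, width_cm=width, height_cm=height, cues=cues)


#: The four preset arenas.  Each carries a large primary cue on the north wall
#: and a smaller secondary cue; environment D carries two wall cues.
PRESETS: dict[str, EnvironmentSpec] = {
    "A": _preset(
        "A", 87.5, 125.0,
        (WallCue("N", 25.0, 40.0, 30.0, pattern=stripes(5)),),
    ),
    "B": _preset(
        "B", 175.0, 125.0,
        (
            WallCue("N", 55.0, 60.0, 30.0, pattern=stripes(6)),
            WallCue("W", 40.0, 16.0, 11.0, pattern=checker(4)),
        ),
    ),
    "C": _preset(
        "C", 175.0, 250.0,
        (
            WallCue("N", 50.0, 70.0, 35.0, pattern=checker(6)),
            WallCue("E", 90.0, 48.0, 11.0, pattern=stripes(3)),
        ),
    ),
    "D": _preset(
        "D", 350.0, 250.0,
        (
            WallCue("N", 120.0, 80.0, 40.0, pattern=stripes(8)),
            WallCue("S", 230.0, 48.0, 16.0, pattern=checker(4)),
        ),
    ),
}


def preset(env_id: str) -> EnvironmentSpec:
    """Return one of the four preset arenas by its label (A, B, C or D)."""
    try:
        return PRESETS[env_id.upper()]
    except KeyError as exc:
        raise KeyError(f"unknown environment preset {env_id!r}") from exc
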