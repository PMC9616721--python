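"""Delimited-text readers and writers for the analysis artefacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environments import EnvironmentSpec, WallCue, checker, stripes
from .ratemaps import Ratemap
from .trajectory import SpikeTrain, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_spikes",
    "read_spikes",
    "write_environment",
    "read_environment",
    "write_ratemap",
    "read_ratemap",
]


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    df = pd.DataFrame(
        {"t": traj.timestamps, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}
    )
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={traj.rate_hz}\n")
        df.to_csv(fh, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().strip()
        rate_hz = float(header.split("=", 1)[1]) if header.startswith("#") else 30.0
        df = pd.read_csv(fh)
    return Trajectory(df["t"].to_numpy(), df[["x", "y"]].to_numpy(), rate_hz)


def write_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    """All units in one file, keyed by unit_id."""
    frames = [
        pd.DataFrame({"unit_id": st.unit_id, "t": st.times}) for st in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(str(uid), np.sort(grp["t"].to_numpy()))
        for uid, grp in df.groupby("unit_id", sort=True)
    ]


_PATTERNS = {"stripes": stripes, "checker": checker}


def write_environment(path: str | Path, env: EnvironmentSpec) -> None:
    doc = {
        "env_id": env.env_id,
        "width_cm": env.width_cm,
        "height_cm": env.height_cm,
        "wall_height_cm": env.wall_height_cm,
        "cues": [
            {
                "wall": c.wall,
                "offset_cm": c.offset_cm,
                "width_cm": c.width_cm,
                "height_cm": c.height_cm,
                "bottom_cm": c.bottom_cm,
                "pattern": "stripes",
            }
            for c in env.cues
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_environment(path: str | Path) -> EnvironmentSpec:
    doc = yaml.safe_load(Path(path).read_text())
    cues = tuple(
        WallCue(
            wall=c["wall"],
            offset_cm=c["offset_cm"],
            width_cm=c["width_cm"],
            height_cm=c["height_cm"],
            bottom_cm=c.get("bottom_cm", 20.0),
            pattern=_PATTERNS.get(c.get("pattern", "stripes"), stripes)(),
        )
        for c in doc.get("cues", [])
    )
    return EnvironmentSpec(
        env_id=doc["env_id"],
        width_cm=doc["width_cm"],
        height_cm=doc["height_cm"],
        wall_height_cm=doc.get("wall_height_cm", 60.0),
        cues=cues,
    )


def write_ratemap(path: str | Path, rm: Ratemap) -> None:
    """Grid layers (rate/dwell/spikes/visited) with a small header."""
    with open(path, "w") as fh:
        fh.write(
            f"# env={rm.env.env_id} bin_cm={rm.bin_cm} unit={rm.unit_id} "
            f"nx={rm.shape[0]} ny={rm.shape[1]}\n"
        )
        for name, grid in (
            ("rate", rm.rate),
            ("dwell", rm.dwell_s),
            ("spikes", rm.spike_count),
            ("visited", rm.visited.astype(float)),
        ):
            fh.write(f"# layer={name}\n")
            np.savetxt(fh, grid, fmt="%.6g", delimiter="\t")


def read_ratemap(path: str | Path, env: EnvironmentSpec) -> Ratemap:
    text = Path(path).read_text().splitlines()
    header = dict(kv.split("=") for kv in text[0].lstrip("# ").split())
    nx = int(header["nx"])
    layers: dict[str, np.ndarray] = {}
    i = 1
    while i < len(text):
        assert text[i].startswith("# layer=")
        name = text[i].split("=", 1)[1]
        rows = [np.fromstring(line, sep="\t") for line in text[i + 1 : i + 1 + nx]]
        layers[name] = np.vstack(rows)
        i += 1 + nx
    return Ratemap(
        rate=layers["rate"],
        dwell_s=layers["dwell"],
        spike_count=layers["spikes"],
        visited=layers["visited"] > 0,
        bin_cm=float(header["bin_cm"]),
        env=env,
        unit_id=header.get("unit", ""),
    )
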