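"""Build ratemaps and detect place fields in the simulated sessions.

Reads the sessions written by 01_simulate_sessions.py, computes
occupancy-normalised ratemaps and odd/even-minute splits per unit, runs
the iterative-threshold field detector, and writes one field table per
arena plus a per-cell field-count table used by the model fits.
"""

from pathlib import Path

import pandas as pd

from placepop import io
from placepop.environments import PRESETS
from placepop.fields import detect_fields, fields_table
from placepop.ratemaps import compute_ratemap, split_session

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sessions = BASE / "sessions"
    all_fields = []
    counts = {}
    for env_id, env in PRESETS.items():
        traj = io.read_trajectory(sessions / f"trajectory_{env_id}.csv")
        trains = io.read_spikes(sessions / f"spikes_{env_id}.csv")
        fields_env = []
        for st in trains:
            rm = compute_ratemap(traj, st, env)
            (ta, sa), (tb, sb) = split_session(traj, st)
            splits = (compute_ratemap(ta, sa, env), compute_ratemap(tb, sb, env))
            fields_env.extend(detect_fields(rm, splits))
            counts.setdefault(st.unit_id, {})[env_id] = sum(
                1 for f in fields_env if f.unit_id == st.unit_id
            )
        table = fields_table(fields_env)
        table.to_csv(BASE / f"fields_{env_id}.csv", index=False)
        all_fields.append(table)
        per_cell = len(fields_env) / max(len(trains), 1)
        print(
            f"env {env_id}: {len(fields_env)} fields "
            f"({per_cell:.2f} per cell), median area "
            f"{table.area_cm2.median() if len(table) else float('nan'):.0f} cm^2"
        )
    count_df = pd.DataFrame(counts).T.fillna(0).astype(int)
    count_df.index.name = "unit"
    count_df["combined"] = count_df.sum(axis=1)
    count_df.to_csv(BASE / "field_counts.csv")
    print(f"wrote per-cell field counts for {len(count_df)} units")


if __name__ == "__main__":
    main()
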