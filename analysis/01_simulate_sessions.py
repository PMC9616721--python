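"""Simulate one animal's recording day: four arenas, scaled durations.

Generates foraging trajectories, a gamma-Poisson place-cell population
per arena, and inhomogeneous-Poisson spike trains, then writes them as
delimited text under results/sessions/.  Durations follow the protocol's
area scaling divided by four so the whole day simulates in seconds.
"""

from pathlib import Path

from placepop import io, synthetic
from placepop.environments import PRESETS

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"
DURATIONS_S = {"A": 225.0, "B": 450.0, "C": 900.0, "D": 1800.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (env_id, env) in enumerate(PRESETS.items()):
        traj = synthetic.generate_trajectory(env, DURATIONS_S[env_id], seed=SEED + i)
        cells = synthetic.generate_population(
            env, 100, alpha=1.0, theta=0.28, seed=SEED + 10 + i
        )
        trains = synthetic.generate_spikes(cells, traj, seed=SEED + 20 + i)
        io.write_environment(OUT / f"env_{env_id}.yaml", env)
        io.write_trajectory(OUT / f"trajectory_{env_id}.csv", traj)
        io.write_spikes(OUT / f"spikes_{env_id}.csv", trains)
        n_active = sum(1 for c in cells if c.fields)
        print(
            f"env {env_id}: {DURATIONS_S[env_id]:.0f} s, "
            f"{n_active}/100 cells with fields, "
            f"{sum(len(t) for t in trains)} spikes -> {OUT}"
        )


if __name__ == "__main__":
    main()
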