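"""Fit field-formation models to the simulated field counts.

Compares the equal-Poisson model (every cell forms fields at the same
rate per m^2) against the gamma-Poisson model (propensities vary across
cells) on the combined-arena field counts from 02_ratemaps_and_fields.py,
fits the field-proportion-versus-area regression, applies the density
adjustment, and extrapolates recruitment to large arenas.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from placepop.environments import PRESETS
from placepop.field_models import (
    adjusted_area,
    fit_models,
    fit_proportion_regression,
    minimum_area_for_recruitment,
    predict_recruitment,
)

BASE = Path(__file__).resolve().parents[1] / "results"
AREAS = {e: PRESETS[e].area_m2 for e in "ABCD"}


def main() -> None:
    counts = pd.read_csv(BASE / "field_counts.csv", index_col="unit")
    combined = counts["combined"].to_numpy()
    total_area = sum(AREAS.values())
    eq, gp, preferred = fit_models(combined, total_area)
    print(
        f"equal-Poisson: tau={eq.tau:.3f} fields/m^2, logL={eq.log_likelihood:.1f}, "
        f"BIC={eq.bic:.1f}"
    )
    print(
        f"gamma-Poisson: alpha={gp.alpha:.3f}, theta={gp.theta:.3f}, "
        f"logL={gp.log_likelihood:.1f}, BIC={gp.bic:.1f}"
    )
    print(f"preferred model: {preferred}")

    reg = fit_proportion_regression(
        {e: counts[e].to_numpy().sum(keepdims=True) for e in "ABCD"}, AREAS
    )
    print(
        f"field proportion vs area: slope={reg.slope:.4f}, "
        f"intercept={reg.intercept:.4f} (A' - A = {reg.intercept / reg.slope:.2f} m^2)"
    )

    recruit = predict_recruitment(gp, AREAS, reg=reg, n_cells=100_000, seed=1)
    a99 = minimum_area_for_recruitment(gp, target=0.99, seed=1)
    report = {
        "equal_poisson": {"tau": eq.tau, "logL": eq.log_likelihood, "bic": eq.bic},
        "gamma_poisson": {
            "alpha": gp.alpha,
            "theta": gp.theta,
            "logL": gp.log_likelihood,
            "bic": gp.bic,
        },
        "preferred": preferred,
        "proportion_regression": {"slope": reg.slope, "intercept": reg.intercept, "r": reg.r},
        "adjusted_area_D_m2": adjusted_area(AREAS["D"], reg) if reg.slope > 0 else None,
        "recruited_proportion": recruit,
        "area_for_99pct_recruitment_m2": a99,
    }
    (BASE / "field_models.json").write_text(json.dumps(report, indent=2))
    print(f"recruitment by arena: { {k: round(v, 3) for k, v in recruit.items()} }")
    print(f"99% of cells recruited above ~{a99:.1f} m^2")


if __name__ == "__main__":
    main()
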