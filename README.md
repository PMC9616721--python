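# placepop

Analysis pipeline for hippocampal place-cell populations recorded while
animals forage in large rectangular arenas, together with synthetic-data
generators that emulate such recordings.  The package asks how place-field
size and density interact with arena geometry: fields are small and densely
packed near walls and large but sparse toward the interior, yet the
population statistics — the proportion of co-active cells, the mean rate,
and the firing-rate distribution — stay constant everywhere, and the rate
at which the population vector turns over tracks the rate of change in the
animal's visual scene.

It is written for systems-neuroscience researchers who want a tested,
scriptable implementation of this analysis chain on either their own
position/spike data or on simulated populations with known ground truth.

## What is implemented

- **Ratemaps** (`placepop.ratemaps`): occupancy-normalised firing-rate maps
  on 4-cm bins, Gaussian-smoothed (σ = 2 bins), with a >10 cm/s movement
  gate; spatial correlation with the 0.01-Hz validity floor; odd/even-minute
  and half/half session splits.
- **Place-field detection** (`placepop.fields`): iterative thresholding from
  1 Hz upward in 0.05-Hz steps over 4-connected components, with size
  (≥10 bins), peak (≥2 Hz), extent (≤half the visited bins) and stability
  (odd/even correlation ≥0.25) gates; in a chain of nested candidates the
  lowest-threshold valid candidate wins unless it has two or more valid
  descendants.
- **Unit selection** (`placepop.units`): place-cell / interneuron
  classification from waveform and stability features, cross-correlogram
  duplicate removal, L-ratio and isolation distance.
- **Decoding** (`placepop.decoding`): Bayesian Poisson decoding with a flat
  prior,
  `P(K|x) ∝ ∏_i λ_i(x)^{k_i} e^{-λ_i(x)} / k_i!`,
  over visited bins of one or several arenas, with 3-minute leave-out
  cross-validated ratemaps.
- **Field-formation models** (`placepop.field_models`): equal-Poisson
  `X ~ Pois(τA)` versus gamma-Poisson `T ~ Gamma(α, θA), X ~ Pois(T)`
  (negative binomial with `r = α`, `p = 1/(1+θA)`), maximum-likelihood fits
  compared by BIC; the field-density area adjustment `A' = A·ρ/b = A + c/b`;
  recruitment extrapolation over a 100,000-cell modelled population.
- **Population statistics** (`placepop.population_stats`): 25-cm
  wall-distance bands; per-band co-active proportion (≥1 Hz) and mean rate;
  Jensen-Shannon divergence between firing-rate distributions across bands
  and temporal halves.
- **Activity dynamics** (`placepop.dynamics`): Savitzky-Golay smoothed
  positions, rates on 33-ms bins with 166-ms Gaussian smoothing, linear
  interpolation to 1-cm path increments, Euclidean population-vector change,
  heading-sector band summaries, path-integration distance, and plain /
  partial correlations.
- **Visual scene** (`placepop.vision`): a CPU ray-cast replica of the arena
  (three 64×64 greyscale cameras, 100° field of view each, 300° total,
  5 cm high, pitched 35° up) and the per-pixel z-scored visual-change
  statistic.
- **Simulated populations** (`placepop.gridsim`, `placepop.synthetic`):
  foraging trajectories, gamma-Poisson populations with wall-distance
  density/width laws, inhomogeneous-Poisson spiking; a 1,271-field uniform
  lattice whose summed activity and vector change are constant everywhere;
  and a boundary-scaled population (density ∝ 1/(d+d₀)², orthogonal width
  ∝ (d+d₀)²) whose activity is homeostatic while its change concentrates at
  walls.

## Worked example

```python
import numpy as np
from placepop import preset, synthetic
from placepop.ratemaps import compute_ratemap, split_session
from placepop.fields import detect_fields

env = preset("A")                                   # 87.5 x 125 cm arena
traj = synthetic.generate_trajectory(env, 900.0, seed=11)
cell = synthetic.SimCell("demo", 2.0, [
    synthetic.GaussianField((25.0, 30.0), 8.0, 8.0, 8.0),
    synthetic.GaussianField((60.0, 95.0), 8.0, 8.0, 8.0),
])
spikes = synthetic.generate_spikes([cell], traj, seed=13)[0]

rm = compute_ratemap(traj, spikes, env)
(ta, sa), (tb, sb) = split_session(traj, spikes)
splits = (compute_ratemap(ta, sa, env), compute_ratemap(tb, sb, env))
for f in detect_fields(rm, splits):
    print(f"field at bin {f.peak_bin}: peak {f.peak_rate:.1f} Hz, "
          f"area {f.area_cm2:.0f} cm^2, stability {f.stability:.2f}")
```

prints

```
field at bin (14, 23): peak 4.7 Hz, area 1312 cm^2, stability 0.94
field at bin (5, 7): peak 3.5 Hz, area 1184 cm^2, stability 0.79
```

— the detector recovers exactly the two planted fields: peak bins (14, 23)
and (5, 7) are within one 4-cm bin of the planted centres (60, 95) and
(25, 30) cm, the ~1200-1300-cm² areas match the 1-Hz footprint of an 8-Hz,
σ = 8 cm Gaussian bump, and both fields pass the odd/even-minute stability
gate.

The numbered scripts under `analysis/` run the full analysis arc on synthetic
data — simulate sessions (01), ratemaps and fields (02), field-formation
model comparison (03), decoding (04), band homeostasis (05), activity
versus visual change (06) — writing tables under `results/`.

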