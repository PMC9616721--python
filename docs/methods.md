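# Methods

This note documents the models and numerical procedures the package
implements, the choices made where the design was open, and what the
synthetic benchmarks do and do not establish.

## Ratemaps and spatial correlation

Position samples (nominal 30 Hz) are assigned to half-open 4-cm square
bins with the origin at the arena's south-west corner.  Dwell time is
samples / sampling rate; each spike is assigned to the bin of its
concurrent position sample.  Only samples with running speed above
10 cm/s contribute.  Speed is estimated by central differences on
Savitzky-Golay smoothed positions (166-ms window; polynomial order capped
at window length − 1, i.e. 4 at 30 Hz) — the same estimate gates every
module, so filters compose consistently.  Dwell and spike grids are
smoothed with a Gaussian kernel (σ = 2 bins, truncated at 4σ, zero-filled
beyond the arena with no renormalisation), and the rate map is their
ratio; bins never visited are reported as missing, not zero.

Spatial correlation is the Pearson coefficient over bins visited in both
maps where at least one map exceeds 0.01 Hz; fewer than 6 valid bins
yields an undefined result.

## Place-field detection

A field is a contiguous region in which firing decays from a single
prominent peak and is stable across visits.  The map is thresholded at
1 Hz and 4-connected components become candidates; each candidate is
re-thresholded 0.05 Hz higher, recursively, building a tree of nested
candidates.  A candidate is valid if it spans ≥10 bins, peaks at ≥2 Hz,
covers at most half of the *visited* bins, and its odd/even-minute
correlation restricted to its own bins is ≥0.25 (fewer than 6 valid bins
counts as unstable).  Parsing runs from the highest thresholds down: in
each chain of overlapping valid candidates the lowest-threshold one is
returned, except that a candidate with ≥2 valid descendant fields is
discarded in favour of the descendants.  The peak gate is re-tested at
every level (the stricter reading).  Field area is 16 cm² per bin; widths
are the extents of the bin set's axis projections; ties for the peak bin
break to the lowest row-major index.

## Poisson decoding

Window spike counts `K = (k_1..k_N)` are scored against per-unit expected
counts `λ_i(x) = f_i(x)·Δt` under independent Poisson likelihoods with a
flat prior over visited bins, evaluated in log space.  Expected rates are
floored at 0.01 Hz so the log-likelihood is finite; `k_i` is the integer
window count (at 1-s windows this coincides with the rate).  Decoded
windows are non-overlapping 1-s windows in which at least half the
position samples pass the speed gate.  Cross-validation removes a
3-minute interval centred on each window before recomputing the maps;
this is done exactly, by subtracting the interval's unsmoothed dwell and
spike histograms from the session histograms and re-smoothing.
Environment identity is the arena owning the globally most probable bin
when the posterior spans all arenas' visited bins.

## Field-formation models

Equal-Poisson: `X ~ Pois(τA)`, one propensity for all cells (MLE is
`mean(X)/A`, verified against the numeric optimum).  Gamma-Poisson:
`T ~ Gamma(α, θA)`, `X ~ Pois(T)`, marginally negative binomial with
`r = α`, `p = 1/(1+θA)`, evaluated via log-gamma functions.  Both are fit
by L-BFGS-B on log-transformed parameters (moment-based start, ftol
1e-12) on combined-arena counts with the combined area, and compared by
`BIC = k·ln n − 2·logL` with n the number of cells.  The likelihood is
not zero-truncated: place cells have at least one field by definition of
the selection step, and the counts enter as observed.

The field-density adjustment fits the per-animal proportion of fields
versus arena area, `y = bA + c`; the density `ρ = (bA+c)/A` rescales the
area to `A' = Aρ/b`, which is algebraically `A + c/b` — an identity the
tests exercise directly.  Recruitment extrapolation draws propensities
for 100,000 modelled cells, draws per-arena counts at `τA` (or `τA'`),
discards cells with no field in any arena, and reports the per-arena
recruited fraction.

## Band statistics and divergence

Bins are banded by the distance of their centre to the nearest wall in
25-cm bands (the innermost band may be partial).  Per bin, the co-active
proportion is the fraction of units whose ratemap value is ≥1 Hz
(adopting the inclusive reading) and the mean rate averages all units;
bands average their visited bins.  Firing-rate distributions pool
1-s-sigma Gaussian-smoothed instantaneous rates (30-Hz grid) of all cells
at samples within a band, keep rates ≥1 Hz during movement, split each
band temporally in half, and are compared with the Jensen-Shannon
divergence in natural log (bound ln 2).  Histograms use 0.5-Hz bins from
1 Hz to the pooled 99.9th percentile with shared edges.

## Population-activity change

Positions are Savitzky-Golay smoothed; per-unit rates on 33-ms bins are
smoothed with a 166-ms-sigma Gaussian; cumulative path length over the
smoothed positions parameterises the session, and rates are linearly
interpolated at 1-cm increments.  Sub-threshold-speed periods split the
path into segments; change — the Euclidean distance between consecutive
population vectors — is never computed across a gap.  Heading sectors are
±45° around the cardinal axes; motion at a sample is "orthogonal" when
its sector's axis matches the nearest wall's normal.  Path-integration
distance accumulates step lengths and resets whenever the animal is
within 12 cm of a wall.  Partial correlation residualises both series on
the covariates (with intercept) and correlates the residuals.

## Visual scene

The arena is rendered as a flat-lit box: floor luminance 0.15, walls
0.05 and 60 cm high, black surround above the walls, and high-contrast
cue panels (stripes/checker) overriding wall luminance.  Three cameras
(64×64 px, 100° field of view horizontally and vertically, square pixels)
sit 5 cm above the floor, pitched 35° up, at yaw offsets −100°/0°/+100°,
covering 300°.  One primary ray per pixel returns the nearest surface's
luminance; there is no lighting model, because the statistic depends on
scene-change structure rather than photorealism.  Visual change is the
per-pixel absolute difference of consecutive frames, z-scored per pixel
over the speed-filtered session (zero-variance pixels contribute zero)
and averaged over pixels.  The rendering is resolution-convergent on the
raw change series (≈2% RMS between 64 and 128 px); the z-scored statistic
is not RMS-stable under resolution doubling — z-scoring divides
near-constant pixels by arbitrarily small deviations — though its
sample-to-sample shape correlates at ≥0.98, so the default 64-px rig is
reported throughout.

## Synthetic data

Trajectories follow a Brownian-rotation heading with an
Ornstein-Uhlenbeck speed process (mean 17.5 cm/s, sd 6, correlation time
1.5 s) and elastic wall reflection.  With the protocol's duration-area
scaling (15 min per 1.09 m²) this covers ≥95% of 4-cm bins, and ~85-90%
of samples exceed the 10 cm/s gate.  Populations draw per-cell
propensities `τ ~ Gamma(α, θA)` and field counts `Pois(τ)`; defaults
α = 1.0, θ = 0.28 m⁻² give ≈1.3 fields per active cell in the smallest
arena, rising with area.  Field centres are uniform (or wall-biased,
density ∝ 1/(d+5 cm)²); widths are fixed (σ = 10 cm) or grow with squared
wall distance, capped at 40 cm; amplitudes are log-normal around 6 Hz
with a 0.05-Hz baseline so silent bins are not identically zero.
Spiking is an inhomogeneous Poisson process realised by thinning against
the cell's intensity bound, with per-cell child seeds for bitwise
reproducibility.

## Reference population grids

Two analytic constructions serve as oracles for the population-level
claims.  The *uniform lattice* places equal Gaussian fields (σ = 12 cm,
5 Hz) on a regular grid spanning the arena plus a 25-cm margin; for the
largest arena the requested 1,271 fields resolve exactly to a 41×31
lattice at 10-cm spacing, centres beyond the walls appearing as cut-off
fields.  Its summed rate and population-vector change are constant to
numerical precision, irrespective of heading.

The *boundary-scaled population* applies the wall-distance laws
separably per axis — centre density ∝ 1/(d_axis+d₀)² and width
σ_axis = σ₀((d_axis+d₀)/d₀)² in the distance to the nearer wall along
that axis (σ₀ = 8 cm, d₀ = 55 cm, capped at 40 cm, with the density law
saturating at the same distance as the width cap so the two always
invert each other).  The separable form mirrors the empirical finding
that field width along an axis follows the wall distance along that
axis; a four-wall superposition was tried first and rejected because
fields of one wall contaminate the orthogonal-motion change near another
wall's bands.  Cut-off rows extend 2.5σ₀ beyond the walls.  With
`normalize=True` the per-axis row density is corrected numerically
(five fixed-point iterations on the 1-D lattice sum) while all
amplitudes stay equal at 4 Hz: equal amplitudes keep the ≥1-Hz co-active
footprint, and hence the co-active fraction, as flat as the summed rate
(amplitude-based normalisation flattens the sum but not the count).  The
4-Hz amplitude places the 1-Hz co-activity threshold near the field's
half-width scale, where count- and sum-homeostasis coincide; it is also
a realistic single-field peak rate.  The non-homeostatic control uses
uniform centre density with the same growing widths and no
normalisation; its summed rate rises ≈70% toward the centre.

## Benchmark scales and what they show

The evaluation benchmarks (`placepop.evaluation`, driven by the test
suite and `scripts/acceptance.py`) run the protocol conditions at desk
scale: durations at one quarter of the protocol's area scaling, populations
of 50-200 cells, 2-3 simulated animals, 50-100 replicates for recovery
statistics, and 600-900-s sessions for the change analyses.  The
instantaneous-change correlation benchmark evaluates the boundary
population's noise-free rates along the foraging path: at these
population sizes the 1-cm change of spike-derived rate estimates is
dominated by Poisson shot noise whose magnitude tracks the inverse of
running speed, which would measure the noise floor rather than the
representational change (the band-homeostasis benchmark, which
time-averages, retains the full spiking path).  Passing these benchmarks
shows the pipeline recovers the constructions' known properties — it
does not by itself certify behaviour on real recordings, where heading
modulation, theta rhythmicity, remapping and cluster contamination are
present but not simulated.

## Known limitations

- The trajectory model has no reward-seeking or wall-following bias
  beyond reflection; dwell is more uniform than real foraging.
- Simulated cells carry no head-direction, speed or theta modulation.
- The renderer has no lighting, shadows or texture beyond procedural cue
  patterns; luminances are nominal, not calibrated.
- Waveform features for unit selection arrive precomputed; no spike
  sorting or waveform extraction is included.
- The gamma-Poisson recovery benchmarks treat the generator's counts as
  observed; fitting counts from the detection pipeline instead (as the
  analysis scripts do) attenuates both parameters because detection is
  imperfect, an effect real analyses share.
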