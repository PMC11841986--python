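# Methods

This note documents the models, estimators, and numerical choices behind
`gridvar`, in the order the pipeline runs them.

## Rate maps and occupancy

Positions are continuous (cm) with the origin at the arena corner; spatial
bins are half-open `[lo, hi)` intervals indexed `[ix, iy]` from that corner
(`ix = floor(x / bin_size)`), with the far arena edge folded into the last
bin. The default bin size is 3 cm (50 × 50 bins for the 1.5 m arena), a
common choice that keeps the autocorrelogram large enough for peak fitting
at spacings of 50–100 cm.

Occupancy assigns each position sample its following inter-sample interval;
the final sample contributes the median interval, so total occupancy equals
the trajectory duration exactly. A bin is *visited* if it holds at least
one sample; unvisited bins are NaN in every derived map, never 0 Hz.

Rate = spike count / occupancy per visited bin, with spike positions
linearly interpolated from the trajectory. Smoothing is mask-aware
(Gaussian-filtered map divided by the Gaussian-filtered mask) so missing
bins neither leak zeros into the map nor bias boundary bins low. The
rate-map smoothing width (default σ = 1 bin) is a config parameter; results
in the variability analysis are driven by SAC peak geometry and are not
sensitive to it within 0.5–1.5 bins.

## Spatial autocorrelogram (SAC)

The SAC is the Pearson correlation of the map with itself at every 2D lag,
using only lags' overlapping visited-bin pairs, with means and variances
computed per lag. All six correlation sums are evaluated with FFT
convolutions, so a full 99 × 99 SAC costs milliseconds — the split-half
resampling below performs ~6000 of them per session. Lags with fewer than
20 overlapping pairs (config `sac_min_overlap`) are missing; a variance
below `1e-9 × max(map)²` per pair marks a lag undefined, and a map that is
constant on its visited bins yields a SAC flagged `degenerate` rather than
silently NaN.

The central peak is masked before fitting. Its radius adapts to the module
scale: the first local minimum of the radially averaged SAC profile,
clamped to [2 bins, 0.3 × half-width]. This removes hand tuning per module
while guaranteeing the inner six peaks survive for spacings up to ~100 cm
at the default resolution.

## Grid fitting

The fitter smooths the masked SAC (σ = 1 bin), finds local maxima above a
threshold (default 0.1 correlation) with a 3 × 3 maximum filter and a 2-bin
plateau-suppression distance, and keeps the six maxima nearest the zero
lag. Peaks are grouped by their *axis representative* — the peak angle
reduced to [−90°, 90°) — and one peak is selected per nominal axis (0°,
60°, 120° → representative −60°) by angular proximity, ties broken toward
the larger SAC value.

Per-axis spacing is peak radius × bin size; spacing in lag bins equals the
lattice constant directly (validated by parameter recovery below), so no
further scale factor is applied. Per-axis orientation is the representative
angle. The overall orientation is a circular mean on the 60°-periodic
domain (angles ×6 → unit-vector mean → ÷6, reported in [0°, 60°)); a plain
arithmetic mean is wrong near the 0°/60° wrap. The overall spacing is the
arithmetic mean of the three axes.

A fit is valid only if (checked in this order): at least six peaks exist
and each axis has a candidate; the three successive angular gaps of the
axes on the 180° circle all lie in [30°, 90°]; and the pairwise ratio of
axis radii lies strictly inside (0.5, 2). Failures carry a reason code
(`too_few_peaks`, `angle_lt_30`, `angle_gt_90`, `spacing_ratio`,
`degenerate_sac`).

Optional 3 × 3 quadratic sub-bin refinement of peak coordinates is off by
default, matching the discrete procedure; with refinement on, noiseless
parameter recovery over λ ∈ [50, 100] cm × θ ∈ [0°, 12°] is accurate to
0.25 cm and 0.15°, and without it to ~1.3 cm and ~0.75° (the bin
quantization floor). The recovery sweep doubles as the calibration closure
for the synthetic generator's wave-vector convention (below).

The grid score correlates the SAC annulus (mask radius out to 1.25 × the
outermost inner-peak radius) with itself rotated 30°–150°:
`min(corr60, corr120) − max(corr30, corr90, corr150)`. It is invariant to
affine rescaling of rates; ideal grids score > 1, spatial white noise ≈ 0.

The boundary-insensitive spacing control re-estimates spacing from the rate
map itself: smooth with σ = 1.5 bins, find field centers
(`peak_local_max`, threshold 20% of the map maximum), and average the pairwise
distances of the most central *approximately equilateral* triple of fields
(side ratio ≤ 1.4 among the six most central). The equilateral guard
matters: when the arena center falls on a lattice vertex, the three
literally nearest fields can include two non-adjacent neighbours (side
ratio √3), inflating the estimate by ~16%. At 3 cm bins, field centers
quantize to ±1.5 cm per axis and boundary-clipped fields shift inward, so
the estimate scatters by a few cm under phase translation; this is a floor
of the method, not noise in the data.

## Split-half variability

Sessions are cut into consecutive 30 s bins from the first timestamp (an
odd trailing bin is dropped), randomly assigned balanced to halves A and B.
All simultaneously recorded cells share each split — there is one
behavioural timeline. Half-recordings inherit per-sample dwell times from
the full trajectory, so gaps between retained segments contribute no
occupancy.

Per shuffle (100 by default), both halves of every cell are fit with the
full-session configuration. A cell is *poor* on a shuffle if either half
fails inclusion. Within-cell variability is |λ_A(i) − λ_B(i)| and the
orientation difference on the 60°-periodic circle (range [0°, 30°]);
variabilities are magnitudes, the only reading under which averaging over
shuffles is informative. Between-cell partners are a fresh uniform random
derangement of that shuffle's surviving cells — no self-pairs, which would
contaminate between with within. Per-cell means are taken over the shuffles
in which the cell (and, for between, its partner) survived.

Cells poor on ≥ 5% of shuffles (strict threshold) are excluded as
unreliable. The population summary reports the four means, the percentage
of cells with between > within (spacing and orientation separately),
one-sided paired Wilcoxon signed-rank tests, and optionally an OLS
regression of within-cell variability on grid score.

Under the null (σ = 0 modules), between > within is a fair coin per cell;
the pipeline's calibration is checked by a binomial test on a simulated
zero-variability module. Power is checked on σλ = 5 cm, σθ = 1° modules,
where > 90% of cells must show between > within for spacing.

## Synthetic grid cells

The ideal rate is the standard three-plane-wave construction

    X(x) = Xmax · (2/3) · [ (1/3) Σⱼ cos(kⱼ · (x + φ)) + 1/2 ],

with wave vectors at angles θ + 30°, 90°, 150° and magnitude
|k| = 4π / (√3 λ), which places nearest-neighbour field centers exactly λ
apart (verified against a dense-grid peak-extraction oracle and by the
fit-grid recovery sweep). X ranges over [0, Xmax], peaking on the lattice.
Renderings of this construction elsewhere sometimes typeset the magnitude
as 4π/(3λ) with unnormalized direction vectors; the convention here is
fixed by the λ-recovery calibration, not by any glyph.

Populations draw λ ~ N(λ̂, σλ) (SD, not variance; non-positive draws are
redrawn), θ ~ N(θ̂, σθ), phases uniform over the arena, and peak rates
N(13, 8) Hz saturated into [2, 30] Hz (point masses at the bounds).
Defaults are the conditions of the large module the analysis targets:
λ̂ = 85 cm, θ̂ = 6°, σλ = 5 cm, σθ = 1° — the measured between-minus-within
variability — in a 1.5 m × 1.5 m arena.

Noisy rate maps are independent Poisson draws per bin with mean equal to
the ideal rate (unit effective dwell, exposed as a multiplier). Full
synthetic sessions add a foraging trajectory — Ornstein–Uhlenbeck velocity
(τ = 2 s, stationary speed tuned to a 15 cm/s Rayleigh mean), dt = 20 ms,
specular wall reflection via path folding — and inhomogeneous-Poisson spike
trains by thinning at the cell's peak rate. The trajectory's only contract
is coverage: a 130-min path visits all 3 cm bins with occupancy CV < 1.
What the generator does *not* emulate: theta-rhythmic and bursty spiking,
correlated noise across cells, conjunctive head-direction tuning, field-to-
field rate differences, and behavioural inhomogeneity (wall-hugging);
passing tests therefore speak to estimator correctness and to the coding
consequences of property variability under Poisson noise, not to every
property of real recordings.

## Linear decoding

Decoding is template matching: ŷ(x) = argmax_y Σᵢ aᵢ(x)·Tᵢ(y), error =
‖x − ŷ(x)‖ between bin centers. Templates average 9 of 10 noisy maps;
each map is held out once. The decoding grid defaults to 50 × 50 bins
(3 cm), so grid granularity is far below the reported errors. Ties in the
argmax resolve to the first bin in row-major order (deterministic;
measure-zero under Poisson noise — float32 accumulation order can flip
near-ties, shifting mean error by ≲ 0.05 cm). Synthetic decoding uses raw
maps; the recorded-session protocol max-normalizes each cell's maps, both
behind one flag. Mean error aggregates over all bins for synthetic maps and
over visited bins for sessions.

Population sweeps draw max(N) cells per population and decode nested
leading subsets, accumulating the score matrix block-wise so each fold
costs one pass over the largest subset; means and SDs are across 25
independent populations (the headline experiment) or fewer in the scaled
sweeps, stated per script. Chance level is the closed-form mean distance
between two uniform points in the square, 0.5214·L ≈ 78.2 cm, also used to
validate the shuffled-template control (each cell's template independently
spatially permuted).

Two-module decoding concatenates populations whose mean spacings follow the
empirical ratios: √2 for consecutive modules, 2 for modules two steps
apart. In the ratio-2 case the larger lattice nests inside the smaller one
up to the inter-module orientation offset (default 15°, configurable; 0°
restores the nesting degeneracy). Cells interleave across modules so nested
subsets stay balanced; a second-module fraction of 0 reduces exactly to
single-module decoding.

The recorded-session protocol cuts the session into 10 contiguous temporal
tenths (the natural reading of "evenly spaced" bins), builds one rate map
per cell per tenth, draws 5 tenths as training per split, and averages
errors over 10 splits × 25 random subpopulations, sizes defaulting to
powers of two up to 64.

## Reproducibility and scale

Every stochastic stage derives an independent stream from one global seed
via `derive_rng(seed, *keys)` (NumPy `SeedSequence` with the keys appended
to the entropy), so any shuffle or population is reproducible in isolation
and runs are bit-stable at fixed seed and config. Saved CSVs carry full
float precision plus a JSON sidecar with config, seed, and package version.

Problem sizes in the test suite and analysis scripts are chosen per
experiment and stated where they deviate from the headline conditions
(e.g. the σ-grid driver uses 3 populations per grid point instead of 25;
the fixed-vs-variable comparison uses 6 independent runs). The headline
decoding experiment itself always runs at full scale: N = 1024, 10 maps,
25 populations, 50 × 50 bins.

## Known limitations

- The SAC spacing estimate is biased high by a fraction of a bin for
  boundary-truncated lattices (the rate-map control is biased low);
  both are reported.
- The reliability filter interacts with module scale: modules with λ
  approaching the arena size lose SAC peaks on half-sessions and reject
  more cells, exactly as with real short recordings.
- The decoder is deliberately linear; its error is an upper bound on what
  an ideal-observer decoder could achieve, and conclusions about
  variability are comparative (variable vs fixed), not absolute.
- The headline decoding error at N = 1024 has a large spread across
  populations (SD ≈ 6 cm over 25 populations); single-population values
  range from ~5 to ~25 cm.
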