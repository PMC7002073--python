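# Methods

This note records the models implemented in `murodyn`, the defaults
that matter, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Two-state displacement model (`murodyn.spt`)

A membrane protein in state *i* ∈ {bound, free} with diffusion
coefficient `D_i` observed at frame interval Δt with per-coordinate
localization error σ_loc produces, at frame lag ℓ, jump magnitudes
with Rayleigh density `r/s_i² · exp(−r²/2s_i²)` where
`s_i² = 2 D_i ℓΔt + 2 σ_loc²`. The factor 2σ² (not σ²) arises because
both endpoints of a jump carry independent localization noise. The
population mixture weights the two components by the bound fraction
`f_b`.

**Fitting.** `fit_two_state` maximizes the summed log-density of the
raw jump magnitudes over all lags present in the sample (`mle`), or
minimizes the squared empirical-vs-model CDF deviation on a 100-point
grid per lag (`cdf-lsq`). Optimization is L-BFGS-B from five fixed
start points spanning the plausible parameter range; bounds are
f_b ∈ [0, 1], D ∈ [0, 5] µm²/s, σ_loc ∈ [0, 0.2] µm. Estimates with
f_b pinned at a bound are flagged.

**Identifiability.** At a single lag with `D_bound` free, `D_bound`
and σ_loc enter only through `s_b² = 2 D_bound Δt + 2σ_loc²` and are
exactly confounded. The default lag set {1, 2, 3} breaks this: the
bound-component scale is lag-independent only when `D_bound = 0`.
`fix_d_bound=True` is the default for routine bound-fraction
estimation; leaving it free is the check that the bound state is
genuinely immobile (fitted values ≤ 10⁻³ µm²/s on immobile-bound
data).

**Uncertainty.** Bootstrap confidence intervals resample whole tracks
(not jumps), respecting the within-track correlation induced by shared
endpoint noise and state persistence. 200 replicates is the
recommended setting for reported intervals; the function default is 0
so that exploratory fits stay fast.

**Jump collection.** Jumps are taken only between detected frames
exactly ℓ apart within one track; pairs spanning a bridged detection
gap contribute nothing at lag 1 (the gap rule).

**Omissions.** No axial-loss (defocalization) correction: both the
model and the simulator are strictly 2-D, so recovery tests are
internally consistent. No hidden-Markov state switching — populations,
not kinetics, are estimated.

## Detection and tracking (`murodyn.detection`, `murodyn.tracking`)

* Bandpass: difference of two Gaussian smoothings (default scales 0.5
  and 100 px), negatives clipped; removes constant background exactly.
  The detection threshold in `auto` mode is the standard deviation of
  the band-passed image — a first-level noise statistic analogous to
  a wavelet-plane threshold. On images dominated by noise it admits
  weak false maxima; an explicit `value` threshold is available.
* Subpixel refinement: isotropic 2-D Gaussian least squares
  (offset + amplitude + centre + σ free) in a 7×7 px window; failed
  fits are dropped and counted in a diagnostics record. Tie-breaks
  between adjacent maxima: higher filtered intensity, then lower row,
  then lower column.
* The directed-motion (MreB) path applies bandpass → 5× bicubic-spline
  upsampling → maxima; the single-particle path applies bandpass →
  maxima → Gaussian refinement.
* Linking: greedy globally-nearest assignment per frame transition
  (candidates sorted by distance, accepted while both endpoints are
  free), which matches a simple nearest-neighbour tracker and is
  deterministic and order-invariant. Defaults: max step 0.3 µm with a
  2-frame gap allowance for single-molecule data; 3 original pixels
  (195 nm at 65 nm/px) with no gaps for directed motion. Gap bridging
  never interpolates positions. Detection capping keeps the last
  15,000 peaks of a movie (the densest, error-prone early frames are
  discarded).
* Temporal smoothing: truncated (±3σ), renormalized Gaussian kernel
  with σ = 1.5 time steps; endpoints use renormalized partial kernels;
  gappy tracks are smoothed per contiguous segment. Track filters:
  ≥ 8 localizations ("more than seven", read strictly) and optionally
  a minimum end-to-end distance.

## Directed-motion statistics (`murodyn.mreb`)

Velocities are per-displacement speeds |Δr|/τ of smoothed tracks
(default τ = 2 s). The flux statistic sums the end-to-end distances of
smoothed tracks whose end-to-end distance is at least 200 nm and
divides by movie duration (default 120 s) and total projected cell
area. End-to-end (not path length) is used both for the qualifying
threshold and the summand; "cell area" is the summed 2-D segmented
footprint, the measurable proxy when one focal plane is imaged.

## Morphometrics (`murodyn.morphometrics`)

The cell axis is the total-least-squares line through the contour
vertices (SVD of the centred vertex cloud); contours whose two
principal values agree within 1% have no meaningful axis and raise.
Poles are vertices whose discrete curvature (circumscribed circle
through the vertex and its ±2 cyclic neighbours) exceeds a threshold,
default 1/diameter-estimate: hemispherical caps have curvature
≈ 2/diameter and clear it, straight flanks sit near zero. Single-vertex
gaps in the cyclic pole set are closed, since pole regions are
contiguous on rods; exactly two arcs are expected and anything else is
flagged, not fatal. Length is the spread of vertex projections on the
axis; the diameter is **twice** the mean perpendicular contour-to-axis
distance of non-polar vertices — the literal mean distance is a
half-width, and doubling makes it commensurate with micrometre-scale
cell diameters.

Fluorescence: `corrected = f⊙I − ⟨f⊙I⟩_bg` (flat-field factor I,
mean over the cell-free background mask), so the corrected background
averages to zero by construction. Concentration is the mean corrected
intensity over the rasterized contour dilated by 1 px (3×3 structuring
element per pixel — membrane-localized signal bleeds one pixel out),
minus the autofluorescence per pixel measured on a non-fluorescent
strain; negative values are reported as-is. The sharpness score is the
variance of the gradient magnitude (central differences), used to drop
out-of-focus cells.

## Population kinetics (`murodyn.kinetics`)

**Doubling time.** log(OD) is fit linearly on contiguous windows
scanned longest-first (earliest start first among equal lengths); the
first window with Durbin-Watson statistic > 1 on its residuals, a
positive slope, and at least 6 points is accepted, and
τ = ln 2 / slope. Windows must additionally span at least one doubling
(`min_fold = 2`): near-flat lag or stationary stretches fit a line
with uncorrelated residuals and would otherwise pass the DW gate while
measuring nothing. Residuals at float-rounding level are treated as a
perfect fit (DW := 2).

**Incorporation kinetics.** The label balance
dS/dt = kin − (γ + kout)·S with S(0) = 0 gives
`S(t) = kin/(γ+kout) · (1 − e^{−(γ+kout)t})`; γ is the culture's
growth rate, prefitted from OD. Cultures are fit jointly with
per-culture kin and one shared kout. Because the model is linear in
kin for fixed kout, the sum of squares is profiled: kin follows in
closed form and kout is found by bounded 1-D minimization (brackets
seeded at 0, γ̄/10, γ̄ and up to 50 γ̄). This reaches the same optimum
as a joint non-linear fit but cannot diverge.

**Osmotic shock.** Extension ratios are post/pre per axis per cell
(1 = no extension); incomplete pairs are dropped and counted. The
permutation test uses the absolute difference of group medians,
enumerating all C(n_a+n_b, n_a) relabelings when that count is ≤ 10⁶
and otherwise using Monte-Carlo with the add-one correction
p = (1 + #{perm ≥ obs}) / (1 + n_perm). Ties at the observed statistic
count as extreme (≥ with a relative tolerance), which keeps the test
exact; under the null the type-I error at α = 0.05 is calibrated (see
the test suite).

**Cross-linking.** percent = 100·(dimer fraction + 2·trimer fraction)
of molar muropeptide fractions that must sum to 1; dimers carry one
peptide bridge and trimers two.

## Synthetic data (`murodyn.synthetic`)

The generators define the conditions under which every estimator is
validated:

* Two-state tracks: each particle keeps one state for its lifetime (no
  switching — the fit estimates populations, and lifetime-scale
  switching would be a different model); Brownian steps of the state's
  D; independent N(0, σ_loc²) noise per coordinate per frame; track
  lengths geometric with configurable mean (default 8), minimum 2 —
  a photobleaching-like stand-in, not a measured distribution.
  Optional confinement reflects true positions specularly inside the
  axis-aligned rectangle length × diameter (coordinate folding; exact
  for arbitrary step sizes). The rectangle, rather than a stadium,
  keeps reflection closed-form; at the sub-cell diffusion scales used
  in tests the difference is immaterial.
* Directed tracks: constant transverse speed with specular reflection
  at the lateral boundary, plus localization noise. Constant projected
  speed is a simplification of circumferential motion seen in
  projection (the true projection modulates speed sinusoidally).
* Spot movies: isotropic Gaussian PSF of given σ and peak amplitude on
  a constant background; Poisson and Poisson+Gaussian noise models.
  No blinking, defocus or EM-gain statistics.
* Growth curves: flat lag, exponential with the given doubling time,
  hard cap at the stationary OD, additive Gaussian noise.
* Incorporation series: exact ODE solution above, optional Poisson
  counting noise.
* Shock tables: per-cell pre-shock dimensions lognormal around typical
  *E. coli* values (0.9 µm short axis, 3 µm long axis); post/pre
  ratios lognormal with the requested mean and ≈sd.

Coordinates are physical (µm), origin at the image corner; pixel
(i, j) has its centre at ((j+0.5)·px, (i+0.5)·px); px defaults to
0.065 µm. All generators are bitwise-deterministic given their seed
and emit ground truth (states, true trajectories, parameters)
sufficient to score recovery without re-simulation.

Passing recovery tests on these generators shows the estimators are
correct under the stated model; it does not certify behavior under
photophysics, 3-D effects, segmentation errors or state switching,
which the generators deliberately omit.

## Problem sizes and reproducibility

Recovery tests use 10⁴–10⁵ jumps (bound-fraction spread ≈ 0.5–1
percentage point at these sizes), 20 seeds for noisy-kinetics
medians, 2,000 null datasets for permutation-test calibration, and
10⁶-sample Monte-Carlo oracles for folded-normal step inflation.
`scripts/acceptance.py` uses 20,000 tracks (~1.4×10⁵ lag-1 jumps) per
two-state condition and 8,000 for the free-`D_bound` check; sub-seeds
are derived from the single `--seed` via a seed sequence, so runs are
exactly reproducible.

## Known limitations

* The bound/free mixture assumes independent jumps; within-track
  correlation (shared endpoint noise, state persistence) inflates
  estimator variance relative to the iid ideal, which the bootstrap
  over tracks absorbs into the intervals.
* The greedy linker is not globally optimal (no Hungarian assignment,
  no motion model); at the densities validated here ≥ 98% of links
  match ground truth, but crowded movies degrade it — hence the
  detection cap.
* Morphometrics assumes straight rods: no curved-centerline width
  profiles, no 3-D shape.
* The threshold segmenter expects bimodal phase-contrast intensity and
  is a stand-in for a dedicated contour package; precomputed masks or
  contours can be supplied instead.
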