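# Methods

This note documents the models, estimators and numerical choices behind
`uexmtools`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Measurement model

All measurements are made on line profiles: per-channel intensity versus
position (nm) along a user-defined line, averaged across a configurable
width (for longitudinal scans the width should cover the centriole).
Profiles and images live in *expanded* (gel) space; biological dimensions
are obtained exactly once by dividing by the expansion factor
(`measured gel disk diameter / 4 mm punch diameter`). Correcting an
already-corrected measurement raises, so the factor cannot be applied
twice silently. The electron-microscopy centriole diameter, 200 ± 12 nm,
is carried on the calibration object as the isotropy reference band.

### Half-maximum extent detection

Profiles are first up-sampled by a subdivision factor (default 3, linear
interpolation), mirroring the practice of artificially decreasing the
pixel size before picking signal extremities. The signal extent of a
channel is delimited at `threshold = baseline + h·(peak − baseline)` with
`h = 0.5` by default:

- **Baseline.** The median of the outer 10% of samples at each profile
  end. This makes the 50%-of-peak rule robust to camera offset and
  reduces to the plain rule when the baseline is zero.
- **Crossing scan.** Scanning inward from each profile end, the first
  threshold crossing is taken, so interior noise dips below half-max do
  not split the extent. Each crossing is localised by linear
  interpolation between the two bracketing samples (sub-pixel).
- **No signal** (peak not above baseline) is a distinguishable outcome
  (`None`), not an exception: a flat marker channel is a legitimate
  biological observation (marker absent), while a flat tubulin channel in
  a side view is an error.

Lengths are `end − start` of the extent. Bottom-view diameters come in
two conventions, both provided because fluorescence does not fix one:
**peak-to-peak** (default; wall-centre distance, each peak refined by a
3-point quadratic fit) and **outer-half-max** (outermost crossing
distance, always ≥ peak-to-peak). Profiles in which no channel shows the
two wall peaks of a ring crossing are rejected; a channel that projects
to a single central peak (a solid cap seen end-on) simply gets no
diameter. Relative marker positions subtract the tubulin start (the
reference protein, shifted to 0); negative marker starts are allowed
(caps protruding below the wall). Position summaries report mean ±
sample sd (n−1; a single record reports sd 0 with an explicit flag) and
both a per-centriole growth curve and an optionally binned version,
since scatter versus binned means is a presentation choice.

## Synthetic data generator

The generator emulates expanded centrioles as seen in projected
two-channel images: in side view the cylinder wall projects to two
parallel bars separated by the wall-centre diameter; in bottom view to an
annulus. Markers are a proximal **cap** (solid block), a **proximal
ring**, or a **sleeve**, at their own diameter and longitudinal extent,
with an offset relative to the proximal wall end that may be negative.

- **Rendering.** Structures are drawn in continuous gel-space
  coordinates (biological nm × expansion factor) and area-sampled onto
  the pixel grid — analytically in 1D (a box convolved with a Gaussian
  and averaged over a pixel has a closed form in Φ), by 4×4 supersampling
  in 2D — before PSF convolution, to avoid aliasing bias in diameter
  tests.
- **Noise.** `Poisson(photon_scale · ideal) + N(0, read_noise²) +
  background`, a standard shot-noise/read-noise camera model. A
  `shot_noise=False` switch makes fully noiseless renders expressible.
  Identical parameters and seed give bit-identical output.
- **Defaults** (chosen once as realistic spinning-disk U-ExM conditions):
  pixel 105 nm and PSF σ 60 nm in gel space, expansion factor 4,
  ~200 photons at the structure peak, read noise 3 counts, background
  offset 10 counts, wall thickness 40 nm (antibody-decorated microtubule
  wall). At these settings the peak SNR is ≈ 13.
- **Growth series.** Procentriole lengths are uniform over a range; the
  marker is present iff length ≥ onset, and its extent grows as
  `min(max_extent, 0.5·(length − onset))` — the data only constrain
  presence versus length, so any monotone rule serves, and this one is
  simple and testable. Each record carries a `detectable` flag (predicted
  peak SNR ≥ 5 under the imaging model), because a marker much shorter
  than the PSF is physically below the detection limit even though it is
  "present" in ground truth.
- **Cyst counts** are multinomial draws from the lineage mixture
  distribution (below).

What passing tests on these data show: the estimators are unbiased and
calibrated under a faithful geometric model with realistic noise. What
they do not show: robustness to structured artefacts absent from the
generator — non-isotropic expansion, out-of-focus light, neighbouring
structures, orientation errors from manual picking, chromatic offsets,
or 3D tilt (the generator is strictly 2D in-plane; see Non-modelled
features below).

## Appearance-point (onset) estimation

Presence of a marker is called by a k-sigma rule (default k = 3): the
profile is smoothed with a 3-sample moving average (so single-sample
noise spikes cannot masquerade as peaks), the baseline level is the
median of the outer 10% of samples at each end, and the noise sd is
estimated robustly as the larger of the median-absolute-successive-
difference estimator (insensitive to the few signal-bearing samples) and
the tail sd, propagated through the smoothing. On growth series at the
default imaging conditions this reproduces ground-truth presence in
≥ 99% of detectable cases, with errors confined to false positives on
very short profiles.

The onset is the midpoint between the longest length without the marker
and the shortest with it. When the two groups interleave the formula is
still applied but flagged (`overlap_flag`) rather than silently switching
estimator. Uncertainty comes from a seeded percentile bootstrap
(default 1000 resamples; resamples missing one group are redrawn and
counted).

**Known limitation.** The midpoint estimator is a function of two sample
extremes, and the with-replacement bootstrap is inconsistent for
extremes: the 95% percentile interval covers the true onset in only
~85–87% of replicate simulations (n = 100, uniform lengths 40–400 nm,
onset 120 nm) rather than the nominal 95%. The interval is therefore
mildly anti-conservative and should be read as an indicative, not exact,
uncertainty; a subsampling bootstrap would be calibrated but is not what
this estimator implements. The point estimate itself is accurate to
about half the mean inter-sample gap.

## Intensity quantification

ROIs are either the thresholded connected component containing a seed
point — Otsu computed on a 64×64 window around the seed, because
centriole spots are sparse in large fields, or a fixed threshold — or an
axis-aligned square. The per-pixel background is the median of an
annulus around the ROI (mask dilated by 5 px minus dilated by 2 px) by
default, or a global 10th percentile. `net = integrated − background ·
area`; the internal-control channel is quantified on the *same* mask and
`normalized = net / control_net`, which cancels per-cell staining and
acquisition variability. Batch mode supports blind scoring: measurement
tables carry shuffled anonymous ids and no genotype; a separate key table
de-anonymises exactly.

## Cyst-lineage inheritance model

A goniablast with one engaged centriole pair (2 centrioles) undergoes
four symmetric mitoses (generations 0→4, 1→16 cells). Per division:
duplication doubles the count if active, then segregation splits it as
evenly as possible (⌈n/2⌉, ⌊n/2⌋ — the minimal consistent extension
beyond the 1- and 2-centriole cases that actually occur). Duplication is
active before the failure-onset stage and inactive from it on; with no
failure, each final cell duplicates once more (pre-meiotic S phase),
giving 16 cells with 4 centrioles. Failure from the 8-cell stage yields
16 × 1C; failure at the 4-cell stage yields, per failing cell, 4
descendants split 2 × 1C / 2 × 0C. Hence a mixture with fraction `f` of
final cells descending from 4-cell-stage failures has `P(0C) = f/2`,
`P(1C) = 1 − f/2`. The fit maximises the multinomial likelihood over
`f ∈ [0,1]` by a 201-point grid plus bounded golden-section refinement
(xatol 1e-10) and reports the closed form `f̂ = 2·n₀/(n₀+n₁)` (clipped
to [0,1]) alongside as a check; classes outside {0C, 1C} are logged and
excluded as a tolerated residual (e.g. escaper pairs). Engagement state
is not modelled — only counts are scored. Cells escaping knockdown could
be added as a third mixture component, but it is off by default to keep
the model identifiable from a two-class table.

## Statistics

- **Fisher exact.** 2×2: two-sided p is the sum of hypergeometric
  probabilities of all tables with the observed margins at most as
  probable as the observed one, with the customary 1+1e-7 relative slack
  on the comparison (the R convention; a doubled-tail variant is
  available behind a flag since some commercial software doubles the
  smaller tail). r×c: full enumeration over tables with fixed margins for
  grand totals ≤ 200, otherwise seeded Monte Carlo over
  margin-preserving permutations with the add-one estimator
  `(1 + hits)/(reps + 1)`.
- **Wilcoxon rank-sum**, two-sided, unpaired, mid-ranks for ties. Exact
  mode enumerates all ⟨N choose m⟩ assignments of the rank sum (automatic
  for m+n ≤ 12 without ties; the enumeration itself handles mid-ranks,
  so forcing exact mode with ties is permitted). Otherwise a normal
  approximation with tie-corrected variance and 0.5 continuity
  correction. No p-value floors are applied anywhere — displayed floors
  like "p = 2×10⁻¹⁶" in statistical software are artefacts, not values to
  reproduce.
- **Box summaries** use linear interpolation between order statistics
  (type 7, numpy's default; the convention is stated because percentile
  definitions differ) and report median, quartiles and 10th/90th
  percentile whiskers.

All of this is implemented from first principles; library
implementations (scipy) appear only as independent oracles in the test
suite, where the two routes agree to machine precision.

## Problem sizes and numerical choices

The test suite measures 50 synthetic side views and 50 rings for
parameter recovery (mean corrected length within 15 nm of the 390 nm
truth; mean peak-to-peak diameter within 10 nm of 240 nm), runs 200
replicate onset simulations with 1000 bootstrap resamples each, 2000
null replicates for the Wilcoxon level check, and 40 seeds for the
power check of the normalized-intensity comparison (0.6× effect,
n = 30/30, α = 0.01) — sizes chosen to make the stochastic assertions
stable at desk scale. Sub-pixel detection is verified against a
1000×-oversampled brute-force crossing finder to 1e-6 nm on 500 random
noiseless plateau profiles.

Degenerate inputs are handled explicitly: flat channels are "no signal";
profiles need ≥ 3 samples; single-peak bottom-view profiles are
rejected; empty ROI components, empty masks, zero margins in contingency
tables and empty samples raise validation errors. Peak refinement clamps
the quadratic offset to ±0.5 sample. The blur-monotonicity property
(wider PSF never narrows the measured extent) holds to within 0.5 nm of
discretization slack; for PSFs approaching the structure length the
half-max width of a blurred box is not exactly monotone, a property of
the mathematics rather than of the implementation.

## Non-modelled features / limitations

No 3D rendering or tilt, no ninefold microtubule-triplet substructure,
no chromatic aberration, drift, uneven illumination or spot detection;
centriole picking and orientation are assumed given (as annotations).
The bootstrap undercoverage discussed above is the main statistical
caveat.
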