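# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `burstkin`, in the order the pipeline runs.

## Synthetic data: what the generator emulates

The `synthetic` module produces every input class the analysis consumes,
with exact ground truth:

* **Walker ensembles** for SMT-style analysis. Three motion models:
  Brownian (per-axis step variance 2·D·dt), confined (Brownian steps
  reflected at the disc of radius Rc about the start point) and fractional
  Brownian motion with stationary increments and E[MSD(dT)] = 4·D·dT^α (2D
  convention; increments sampled exactly from the Cholesky factor of the
  fractional-Gaussian-noise covariance, Hurst H = α/2). Localization error
  is Gaussian, independent per frame and axis, added *after* reflection —
  it models camera noise, not motion, so the hard confinement invariant
  (no true position beyond Rc) is preserved. Photobleaching is modeled as
  a fixed track lifetime in frames (deterministic, simpler ground truth)
  rather than an exponential lifetime.
* **Multi-channel burst movies**: non-overlapping elliptical nuclei on a
  grid, each holding one confined locus walker; the MS2 focus is rendered
  at the locus position only during the on-intervals of a per-nucleus
  telegraph schedule (exponential on/off dwells; off-gaps shorter than one
  frame are merged because they are invisible at the sampling rate). Spots
  are Gaussian with configurable PSF width; nuclei carry a static smooth
  texture; noise is Poisson shot noise plus Gaussian read noise. `snr` is
  the single-spot peak amplitude over the background noise σ. Burst foci
  default to 3× that reference (`on_intensity=3`): an MS2 focus aggregates
  tens of coat-protein-bound stem-loops over multiple nascent transcripts
  and dominates the diffuse nucleoplasmic reporter. This matters because
  the burst-call rule is an *absolute* one (below); with foci at 1× the
  single-molecule reference the rule has no valid operating point at any
  background level, which is physically right — bursts are called because
  they are far brighter than single molecules. The default fixture uses a
  background of 30 counts.
* **Organelle masks** as unions of discs (speckle-like blobs), FISH-like
  spot coordinate sets, and **rigid-body drift injection** (per-frame
  rotation about the image centre followed by translation), with the
  applied transforms recorded in the ground truth.

What the generator does *not* emulate: 3D point-spread functions and
z-sectioning (the simulation is 2D, matching max-projected/single-plane
analysis), camera gain and offset calibration, spectral bleed-through,
inhomogeneous nuclear backgrounds beyond smooth texture, and interacting
loci. Passing tests therefore demonstrate algorithmic correctness and
recovery under the stated noise model — not robustness to every artefact of
real microscopy.

Identical `SimulationConfig` (including `rng_seed`) reproduces every array
bit-for-bit.

## Segmentation

Burst-movie nuclei: Gaussian blur → top-hat background subtraction →
mean auto-threshold → watershed split → area selection. FISH nuclei:
maximum z-projection → top-hat → Gaussian blur → Huang fuzzy-entropy
threshold → removal of particles below the minimum area → hole filling →
adjustable watershed (h-maxima of the distance transform at the configured
tolerance, default 6). Auto-threshold methods are implemented from their
published definitions (mean of pixels; Huang & Wang fuzzy entropy; isodata
intermeans for "default") and applied strictly-greater.

Numerical choices:

* "Rolling-ball" background subtraction is realised as a grayscale top-hat
  with a disc structuring element of the quoted radius; for radii above
  5 px the disc is decomposed into a footprint sequence (orders of
  magnitude faster, output differences far below threshold sensitivity).
  Oversized radii degrade gracefully on small frames.
* The DoG band-pass uses σ = radius directly for the quoted radii (12/6
  for burst movies); the convention of the original macros is not
  recoverable, so both radii are exposed in `SegmentationParams`.
* Area selections (40–200 for nuclei, <20 for FISH particles) are areas in
  px² at a reference pixel size and scale with (pixel-size ratio)².
* Spot calls are 8-connected strict maxima of the DoG response above
  threshold; one spot per connected above-threshold patch, positioned at
  the DoG-weighted subpixel centroid of the patch. Coordinates are 0-based
  pixel indices converted to µm.

Per-nucleus burst detection first suppresses everything outside the target
nucleus to 0.9× its median intensity (suppression is idempotent and leaves
interior pixels untouched), then thresholds the DoG response at
`5 + 0.55 × median` — exact to machine precision by construction. DNA spots
in tracking movies threshold the DoG at k·SD of the channel (k
configurable, default 3, applied after extranuclear suppression); tracking-
movie RNA spots use a fixed absolute threshold; organelles use a mean
auto-threshold of the DoG.

## Tracking

Frame-to-frame linking is optimal bipartite assignment (Hungarian
algorithm) on squared displacements, gated at the maximum linking distance;
gap closing is a second pass joining segment ends to later segment starts
(frame gap ≤ max, end-to-start distance ≤ closing distance), candidates
consumed greedily in (gap, distance) order. No splitting or merging.
Defaults: 0.4 µm link, gap 3, 0.6 µm close, minimum 5 spots per track;
single-molecule movies drop spots before a settling frame (500 at tracking,
1000 at biophysics) where photobleaching has not yet sparsified the field.
Linking is invariant to input spot order, and on well-separated noiseless
fixtures it reproduces ground-truth partitions exactly.

Burst assembly turns each linked RNA-focus track into one event (nucleus =
majority spot label). In the end-to-end synthetic studies events are linked
with gap closing *disabled*: at the fixture's SNR frame-level detection is
~99.9% reliable, while closing 1–2-frame gaps would merge genuine short
off-periods of the telegraph process. Off-durations are spans between
consecutive events of one nucleus; burst rates are events per nucleus-hour
of observed phase time; phases with no events report missing values, never
zeros.

Drift correction registers a contrast-enhanced nuclear silhouette (Gaussian
blur, Huang threshold, hole filling, dilation; focal signal flattened away;
a faint heavily-smoothed copy of real structure retained for texture) of
each frame onto the reference frame: translation by upsampled phase
correlation, rotation by a coarse-to-fine 1D search within ±2°. A nonzero
rotation is accepted only when it improves the registration error by ≥5%
over the incumbent smaller angle — on noisy near-symmetric nuclei the error
landscape in θ is nearly flat and an unguarded argmin chases noise by
0.1–0.2°. The deliverable contract is the closed-loop residual (<0.5 px RMS
on a stationary locus for translations ≤5 px and cumulative rotations
≤2°), not the per-parameter estimate. Corrections are applied to spot
coordinates directly (no interpolation blur); resampled movies are also
emitted for visual inspection.

## Per-track biophysics

The time-averaged MSD uses all ordered frame pairs at each integer lag;
pairs spanning linking gaps contribute to their true lag and never to the
one-frame lag; lags averaging fewer than 3 displacements are dropped; the
vectorized computation is tested to 1e-12 against an O(n²) enumeration
oracle. Tracks shorter than 5 localizations yield no curve.

α and D come from OLS of log MSD on log dT; with the 2D convention
MSD = 4·D·dT^α, α is the slope and D = exp(intercept)/4. **Estimator bias,
quantified.** On short noisy tracks the plain all-lag fit is biased low by
two well-understood effects: (i) static localization error adds a constant
4·σ_loc² to every lag — at D = 0.1 µm²/s, dt = 5 ms, σ_loc = 20 nm this
floor is ~80% of the one-lag MSD, flattening the short-lag slope; (ii) the
time-averaged MSD at lag k has only ~n/k effectively independent
displacements, so the long lags scatter wildly and are downward-biased
after the log transform. Simulations at those settings give median α ≈ 0.75
(≈ 0.86 even without noise) and median D ≈ 0.045. Neither lag truncation
nor weighting alone repairs this; the combination of subtracting the
(known or estimated) noise floor and fitting only the first few lags does.
`fit_alpha_diffusion` therefore defaults to the plain all-lag estimator —
the transparent choice for comparisons *within* a dataset, where a common
bias cancels — and exposes `noise_floor_um2` and `max_lags`
(`RECOVERY_MAX_LAGS = 8` suits tracks of a few dozen frames) for recovery
studies and absolute calibration; under those corrections the same
simulations give median α ≈ 0.99 (Brownian), ≈ 0.49 (fBm α = 0.5) and
median D within 10% of truth. The feature pipeline for clustering keeps the
plain defaults.

The confined model MSD = Rc²(1 − exp(−4·Dr·dT/Rc²)) is fitted by nonlinear
least squares in linear MSD space, weighted by √n_pairs, initialized at
Rc₀ = √(max MSD) and Dr₀ = (first-lag slope)/4, with tolerance 1e-10 and
positivity bounds; non-convergence flags the track's features missing. The
source procedure nominally fed log-converted values to the nonlinear fit;
fitting the stated formula to log values is ill-defined at the plateau, so
linear space is the default and `fit_space="log"` is provided for audit.
Reflection in a disc is not the model the fit assumes, so the fitted Rc of
reflected-Brownian ensembles is validated only to ±25% (measured median
error ≈ 0.3%: the pairwise-stationary plateau of a disc of radius R is R²).

Residence durations are the time (frame offset × interval) to the first
excursion beyond 0.25/0.5 µm of the track start, or the full observed
duration if never exceeded. Single-frame displacements use consecutive
frames only. Tracks with any missing feature are excluded from clustering
(complete-case) and counted.

## Mobility-state clustering

Features: D, α, Rc, Dr, MSD at the first lag, residence within 0.25 µm.
The heavily right-skewed features (D, Rc, MSD@dT1) are log-transformed
before clustering (config-switchable); the source analysis is silent on
transformation, so this is a documented choice made for mixture normality.
Training sets are condition-balanced random subsamples (seeded,
reproducible, with the balancing record emitted).

The GMM is full-covariance with k = 6 by default, initialized from k random
data points refined by ≤20 k-means iterations (best of 10 restarts) and
≤20 EM iterations; singular covariances are ridge-regularized. Ward
clustering runs on z-scored features (training-set statistics); its labels
train a multi-class SVC with Laplacian kernel exp(−γ‖x−y‖₁), γ = 1/d,
cost C = 8. Components/clusters are canonically reordered by *descending*
mean D, so the last cluster index is always the slowest, most confined
state and indices are comparable across runs and methods. k is never
auto-chosen: `model_selection_report` emits silhouette and
between-condition divergence per candidate k so the choice can be audited.
Fixed seeds give bit-identical persisted models.

Fold changes are per-cluster fraction ratios between two conditions with
bootstrap CIs (resampling tracks, default 1000 replicates); empty
denominator clusters report missing, never infinite. When per-cell grouping
exists, per-cell cluster fractions are compared by two-tailed t-test.

## Burst- and phase-resolved mobility

A DNA-track frame is burst-labelled iff it lies inside an on-interval of a
same-nucleus burst event (frame-level containment, preserving within-track
transitions); maximal equal-label runs become segments; segments shorter
than 3 frames (configurable) are excluded from displacement statistics.
Phase windows default to pre (<0), acute 0–120 min and chronic ≥160 min
relative to stimulation, with the 120–160 min transition deliberately
unlabeled; an alternative preset anchored on the observed bursting peak
(acute 24–132 min) ships alongside, and neither is silently preferred.

Mobility comparisons use cells (nuclei) as the statistical unit: per-cell
mean single-frame displacement per state, paired two-tailed t-test across
cells observed in both states (falling back to unpaired, and reporting
which), with the conventional significance markers (* <0.05 to ****
<1e-4). The normalized displacement time course bins displacements by
mid-frame time and divides by the pre-stimulation mean (or first bin when
no baseline exists); bins with fewer than 3 loci are flagged.

## Organelle proximity

Signed distance = external − internal Euclidean distance transform,
evaluated at the pixel nearest the spot centroid (sub-pixel interpolation
would add less than half a pixel and complicate the exhaustive oracle).
Positive means outside. The convention never takes the value 0: adjacent
pixels across the boundary jump from −1 px to +1 px, and the map is
1-Lipschitz per pixel step within either region. Periphery association is
quantified as the fraction of spots in a thin shell just outside the edge
(default 0–0.3 µm).

The burst–proximity null uses circular permutation of the distance series
within each cell, because both series are autocorrelated and i.i.d.
shuffling would be anticonservative. Circular shifts are an exchangeable
null only for stationary series; the calibration study therefore models
proximity as a stationary AR(1) fluctuation (a confined locus's distance to
an organelle is bounded), under which permutation p-values are uniform by
the KS test. Both parametric (Pearson/Spearman/point-biserial) and
permutation versions are reported, since the original figure's statistic is
unspecified.

## Problem sizes of the validation studies

The packaged studies use 200 random tracks for the MSD oracle, 1000-track
ensembles (50 frames, 5 ms, 20 nm noise) for α/D recovery, 500 reflected-
Brownian tracks of 200 frames for Rc recovery, one 20-nucleus 60-frame
256×256 movie at SNR 5 for end-to-end burst calling, 36 walkers for linking
exactness, a 10-frame 128×128 movie for the drift closed loop, 1050
balanced rows for clustering recovery, 20 simulated cells × 460 frames for
the burst-coupled mobility design, and 50 random masks plus 200 replicates
× 199 circular permutations for the signed-distance machinery. These sizes
give stable medians and test power while keeping a full validation run
under a minute.

## Known limitations

* 2D only, throughout: simulation, segmentation, distance transforms and
  linking. Single-plane/max-projected data is the intended regime.
* The confined-fraction generative model (disc reflection) is a choice; the
  source quantifies confinement only through the fitted (Rc, Dr).
* No hidden-Markov within-track state segmentation, no jump-distance
  fitting, no motion-blur correction of D, no probabilistic (MHT) tracking,
  no machine-learned segmentation.
* The absolute burst rule (5 + 0.55·median) is tied to the intensity scale
  of the original acquisitions; on other data the offset/slope and the DoG
  radii must be recalibrated (all are config).
* Drift rotation is estimated by exhaustive 1D search; rotations beyond the
  ±2° window or strong non-rigid deformation are out of scope.
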