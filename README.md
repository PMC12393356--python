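# burstkin

Quantitative kinetics of transcriptional bursting and chromatin locus
mobility from live-cell imaging.

`burstkin` is a tested, reusable implementation of the analysis chain used
to ask how a gene's transcriptional activity relates to the physical
behaviour of its locus: MS2/MCP burst calling in time-lapse movies,
drift-corrected tracking of a tagged DNA locus, per-track diffusion
biophysics, clustering of single-molecule trajectories into mobility
states, and signed-distance quantitation of locus/FISH-spot proximity to
nuclear organelles (speckles, matrix networks). It is aimed at groups doing
live imaging of endogenous gene loci and single-molecule tracking (SMT) of
nuclear factors who want the full pipeline — from calibrated TIFF stacks to
statistics — as importable, unit-tested Python rather than a chain of
ImageJ macros and R scripts.

Every stage can be exercised end-to-end on synthetic movies and walker
ensembles with exact ground truth (the `synthetic` module), so the whole
pipeline is testable without any microscopy data.

## The models at the core

**Burst calling.** Nuclei are segmented per frame from the diffuse reporter
signal; within each nucleus everything outside is suppressed to 90% of the
nuclear median (edge-artefact control) and a difference-of-Gaussians
response is thresholded at

```
threshold = 5 + 0.55 × (nuclear median intensity)
```

Above-threshold foci linked over time (linear-assignment tracking) become
burst events with number, frame, and duration; off-periods are the spans
between consecutive events of one nucleus.

**Track biophysics.** For each track the time-averaged mean squared
displacement over all frame pairs at lag dT (lags with fewer than 3
displacements dropped) feeds two fits:

```
MSD(dT) = 4·D·dT^α                      (log–log OLS: α = slope, D = exp(intercept)/4)
MSD(dT) = Rc²·(1 − exp(−4·Dr·dT / Rc²)) (nonlinear least squares)
```

together with the MSD at the first lag and the residence durations within
0.25 and 0.5 µm of the track start — six parameters per track. α < 1 marks
subdiffusive/confined motion; Rc² is the confinement plateau.

**Mobility states.** Tracks are clustered in the six-parameter space with a
full-covariance Gaussian mixture (k = 6 by default) and, independently,
Ward hierarchical clustering whose labels train a Laplacian-kernel SVM
(C = 8) for cross-experiment assignment. Clusters are canonically ordered
by descending D so "the last cluster" is always the slowest, most confined
state; per-condition cluster fractions and bootstrap fold changes quantify
treatment effects.

**Burst-coupled mobility.** DNA-locus tracks are segmented frame-wise into
burst vs non-burst (by overlap with same-nucleus burst events) or into
pre/acute/chronic stimulation phases (defaults 0–120 min and ≥160 min after
hormone addition), and per-cell mean single-frame displacements are
compared with paired two-tailed t-tests.

**Organelle proximity.** Binary organelle masks yield internal and external
Euclidean distance transforms; a spot's signed distance is external −
internal (positive outside, negative inside). Burst–proximity association
is tested with point-biserial correlations against a circular-permutation
null that preserves autocorrelation.

## Worked example

Simulate a mixed ensemble of free and confined walkers at the 5 ms SMT
frame interval and compute the six biophysical parameters:

```python
from burstkin import SimulationConfig, WalkerSpec
from burstkin.synthetic import simulate_tracks
from burstkin.biophysics import features_table

cfg = SimulationConfig(frame_interval_s=0.005, n_frames=80, rng_seed=0,
                       localization_noise_um=0.02)
specs = (
    [WalkerSpec(model="brownian", D_um2_s=0.1, lifetime_frames=80)] * 150
    + [WalkerSpec(model="confined", D_um2_s=0.1, Rc_um=0.15,
                  lifetime_frames=80)] * 150
)
tracks = simulate_tracks(specs, cfg)
for t in tracks[:150]:
    t.condition = "free"
for t in tracks[150:]:
    t.condition = "confined"

feats = features_table(tracks, cfg.frame_interval_s)
print(feats.groupby("condition")[["D_um2_s", "alpha", "Rc_um", "res_025_s"]]
      .median().round(4))
```

which prints

```
           D_um2_s   alpha   Rc_um  res_025_s
condition
confined    0.0067  0.2725  0.1468       0.40
free        0.0654  0.8413  0.4773       0.13
```

Read it as follows: confined walkers are strongly subdiffusive (median
α ≈ 0.27 vs ≈ 0.84 for free diffusion), their fitted confinement radius
(0.147 µm) recovers the generative 0.15 µm, and they stay within 0.25 µm of
their start for most of the 0.4 s observation window while free walkers
escape after ~0.13 s. The plain all-lag log–log estimates of D and α on
short noisy tracks are biased low — this is a property of the estimator,
quantified and discussed in `docs/methods.md`, where a bias-controlled
variant (`max_lags`, `noise_floor_um2`) is described.

A command-line surface wraps the same stages:

```bash
burstkin simulate --out run/ --n-nuclei 6 --n-frames 40 --seed 1
burstkin track --spots run/burst_spots.csv --out run/tracks.csv
burstkin biophys --tracks run/tracks.csv --out run/features.csv --frame-interval-s 120
```

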