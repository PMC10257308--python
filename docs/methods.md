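# Methods

This note documents the models, conventions, parameter choices and known
limitations of `divetrack`, and what the synthetic-trip tests do and do not
demonstrate about field data.

## Sensor model and conventions

Timebase is UTC epoch seconds.  The 1 Hz depth clock is the master grid:
depth drives both dive segmentation and the dead-reckoning timestep, so
acceleration is averaged and the magnetometer linearly interpolated onto it.
Device axes are x surge (forward), y sway (right), z heave (down); level
posture gives a static acceleration of (0, 0, +1) G, pitch is positive
nose-up, roll positive right-side-down, headings are radians clockwise from
true north in [0, 2π).  Body-frame vectors relate to the world
(north-east-down) frame through the yaw–pitch–roll (Z-Y-X) rotation; the
attitude and tilt-compensated-heading formulas in `deadreckon` are the exact
inverse of that rotation, which the test suite verifies by forward-simulating
random orientations and recovering them to 1e−6 rad.

Calibration is per-axis affine only: the pre-deployment rotation sweep's raw
min/max map linearly onto the physical range.  Soft/hard-iron ellipsoid
correction is out of scope, matching the acknowledged limitation of the
tag-processing workflow this package implements; in consequence, real
deployments with significant iron distortion will show heading biases the
package does not model.

## Pre-filters

* GPS fixes from ≤4 satellites are discarded (`min_satellites = 5`), then a
  forward-sequential speed filter drops any fix implying more than 6 m s⁻¹
  from the last retained fix.  The forward-sequential rule makes the filter
  idempotent and deterministic.
* Zero-offset correction: the baseline is the rolling 10th percentile of
  near-surface samples (raw depth < 3 m) in a 2-h window, interpolated across
  dives and subtracted.  The 10th percentile is robust to wave splash and
  shallow swimming contaminating the surface pool; a 2-h window follows
  drift at realistic transducer rates (metres per day) with bias ≪ 0.1 m.
  For a linear drift of slope b the quantile lags by ≈ 0.4·window·b, so very
  fast drift with a long window would under-correct — the window is
  configurable.  An always-submerged record is returned unchanged with a
  warning.

## Speed model

The reconstruction needs a swim-speed series the tags do not measure.  The
default derives it from the depth rate: s = |dz/dt| / |sin(pitch)| wherever
|pitch| ≥ 5°, clipped to [0, 12 m s⁻¹] (twice the GPS speed threshold).  Two
refinements proved necessary in validation against simulated truth:

* the reliable (steep-pitch) estimates pass through a 5-sample median filter,
  because at phase transitions the attitude and depth-rate smoothing kernels
  disagree for a couple of seconds and the raw ratio spikes;
* near-horizontal samples take the time interpolation of the nearest reliable
  estimates when those lie within 30 s (swim speed is continuous within a
  dive), and only isolated stretches such as surface transit fall back to the
  constant default (1 m s⁻¹).

Without the interpolation rule, every low-pitch second of a bottom phase gets
the constant fallback, which compresses the between-dive spread of measured
bottom distance onto bottom time and pushes their correlation above the
0.750 collinearity cutoff; with it, per-dive speed survives into the metrics.
Multiplicative speed error that remains is largely absorbed by the
georeferencing step, which rescales each inter-fix segment through the fixes.
A VeDBA-proportional speed strategy (`speed_strategy = "vedba"`) is available
as an alternative; it is a pluggable choice, not a claim about any particular
field workflow.

Georeferencing distributes the drift (fix position minus dead-reckoned
position) linearly in elapsed time across each inter-fix segment — the
simplest defensible rule — so the output track passes through every retained
fix exactly.  Degrees↔metres conversion uses equirectangular scaling at the
mean fix latitude; because the same bijection is used in both directions,
fix exactness is independent of the scaling's accuracy.  Step distances are
haversine on the final coordinates.  Ocean-current advection is not
modelled.

## Dive segmentation and metrics

Dives are maximal runs of 20-s-smoothed corrected depth ≥ 5 m (threshold
configurable; the smoothing window is the conventional value for pinniped
TDR records).  The bottom phase is defined operationally as the contiguous
span from the first to the last sample deeper than 80 % of the dive's
maximum depth; brief excursions above the line inside that span remain
"bottom", which is the right behaviour for an animal tracking rugose
substrate.  Spline-based critical-point phase detectors are deliberately
not used: the 80 % criterion is the operative definition here.

Per-dive metrics follow the standard definitions (see README).  Choices the
definitions leave open: depth variability uses the sample (n−1) standard
deviation; colony distance is the mean over bottom samples of the
great-circle distance to the colony; sinuosity is capped at 50 when the
bottom path closes on itself (chord → 0); bottom time is the first-to-last
sample span of the bottom phase.  Because the >80 % span necessarily sweeps
the depth band from 0.8·D to D during entry and exit, the depth-variability
index has a geometric floor of roughly 0.2·D·(tail fraction) even over a
perfectly flat bottom — worth remembering when interpreting small contrasts.

The collinearity screen drops, from the worst-correlated pair (strictly
|r| > 0.750), the member with the larger mean absolute correlation to the
remaining predictors; the rule is deterministic and logged.  Constant
columns are dropped up front.

## Clustering and selection loop

Predictors are z-scored (sample sd).  K-means uses scikit-learn's Lloyd
algorithm with 25 seeded restarts, keeping the best within-cluster sum of
squares — objective-equivalent to the classical Hartigan–Wong procedure up
to local optima, and cross-checked against R's Hartigan–Wong implementation
in the test suite.  Clusters are renumbered by ascending centroid on the
first predictor so "cluster 1" is reproducibly the lower-effort group.  The
cluster number is the argmax of average silhouette width over k = 2..8, ties
toward smaller k.  WCSS + BCSS = total SS is asserted on every solution.

For k = 2 the confirmation step is an ordinary least-squares regression of
the 0/1 cluster indicator on the z-scored predictors, iteratively removing
the single largest-p term above α = 0.05 and refitting; the final adjusted R²
and per-term p-values are reported.  OLS-on-indicator is a documented design
choice (it yields the adjusted-R²-plus-p-value reporting shape used in this
literature); a logistic variant sits behind `family = "logistic"`.  For
k > 2 the loop skips confirmation and logs.  The outer loop (z-score →
silhouette → k-means → stepwise → drop columns → repeat) terminates because
the column set strictly shrinks; with pure-noise predictors the retained set
empties in roughly 83 % of replicates (the best survivor's selection-inflated
p-value lands under α about a sixth of the time — measured by direct
simulation, and the test asserts the measured behaviour).

## The trip simulator

The simulator emulates a central-place benthic forager: surface transit at
1.8 m s⁻¹ along a slowly meandering course (homeward after 60 % of the trip),
dive cycles of fixed-pitch (60°) descent at 1.6 m s⁻¹ vertical rate, a bottom
phase, and ascent, with surface intervals of ~90 s and GPS fix attempts on a
120-s clock that succeed only at the surface.  Two dive archetypes model
low- versus high-effort foraging:

| parameter | low effort | high effort |
|---|---|---|
| bottom duration (s) | 75 ± 20 | 135 ± 20 |
| substrate undulation amplitude | 0–2 % of seabed depth | 6–12 % |
| fine depth texture sd (m) / corr. time (s) | 0.3 / 2 | 1.0 / 8 |
| heading weave sd (rad) / corr. time (s) | 0.25 / 10 | 1.0 / 20 |

Seabed depth per dive is uniform on 30–90 m, per-dive swim speed is normal
(1.1 ± 0.25 m s⁻¹, truncated to 0.5–1.9) and up to 20 % of bottom seconds are
stationary ("grubbing") — all independent of archetype, so bottom speed and
colony distance carry no class signal, mirroring the predictors that the
field analysis discarded.  The bottom depth profile is seabed + sinusoidal
substrate undulation + an Ornstein–Uhlenbeck texture; the heading weaves as
a bounded OU about the entry bearing, so high-effort paths curl strongly
without degenerating into closed loops.  Behavioural sequences are smoothed
over 3 s and pitch re-derived from the smoothed depth and speed, so the
emitted sensors, depth record and true path are mutually consistent (real
animals turn smoothly; without this the gravity filter cannot track
attitude).  Sensors add Gaussian noise (accel 0.05 G plus a 1.4 Hz stroking
signature of 0.15 G, magnetometer 0.5 µT on a 60 µT field, depth 0.15 m plus
a 0.8 m transducer offset).  GPS error scales with satellite count: ≥6
satellites 15 m, 5 satellites occasionally degraded to ≤350 m, 4 satellites
0.3–1.4 km (which is what the satellite filter is for).

These defaults give realized archetype contrasts of ~3 pooled within-class
sd on bottom time, ~2.5 on the depth-variability index and ~2 on sinuosity.
Bottom distance is physically speed × time, which couples its contrast to
bottom time's: the swim-speed spread (CV ≈ 0.25) was chosen so that the
measured bottom-time/bottom-distance correlation sits near 0.7 — below the
0.750 screen most of the time, as in the field data where all seven
predictors survived the screen — at the cost of a distance contrast nearer
1.5–2 sd than 2.  A larger speed spread would decorrelate the pair further
but shrink the distance contrast, and a larger distance contrast would push
the correlation over the screen; the two requirements trade off through one
parameter and the compromise is deliberate (rounding differences can still
flip the screen on borderline trips, dropping one of the pair — the
clustering is robust to either outcome).

A `TripConfig.noiseless(seed)` variant zeroes all sensor noise and the
behavioural draws the reconstruction cannot observe (speed spread, grubbing,
descent bursts; every phase swum at the 1 m s⁻¹ fallback).  It isolates the
attitude/heading/integration/georeferencing chain, which then reconstructs
the path to < 5 m RMS.  What passing simulator tests show: the inversion
formulas, phase segmentation, metric formulas and selection loop are correct,
and the pipeline recovers planted two-mode structure (adjusted Rand index
≥ 0.9 at default contrasts) through the full sensor chain.  What they do not
show: robustness to iron distortion, ocean currents, tag slippage, archetype
mixtures that are not two well-separated modes, or non-Gaussian sensor
faults — none of which the simulator emulates.

## Problem sizes

The simulator's default trip duration is 48 h (the scale of real foraging
trips, ~550 dives).  The test suite and the acceptance script run 3–6 h
trips (≈ 40–80 dives) and a 300–400-row synthetic metrics table for the
selection-loop checks — sizes chosen so the whole suite completes in well
under a minute while leaving every contrast measurable; all results quoted
in the README were produced at those sizes.

## Numerical choices

Rolling means are centred with shrunken edge windows.  Static + dynamic is an
exact decomposition by construction.  Attitude samples with |g| < 0.2 G and
headings with a vanishing horizontal field are flagged and interpolated from
neighbours (circular interpolation for headings).  k-means is seeded;
identical seeds give byte-identical artifacts (asserted).  The collinearity
cutoff is strictly greater-than, implemented with a 1e−12 tolerance so a pair
engineered at exactly r = 0.750 is retained.  Fixes are snapped to the
nearest 1 Hz sample for georeferencing; fixes outside the track's time range
are trimmed with a warning, and fewer than two usable fixes is an error.
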