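# Methods

## Model overview

The package's core assumption is linearity twice over: scalp EEG is a
linear superposition of cortical source activity, and each early
visual area's contribution factorises into a *retinotopic topography*
(fixed per stimulus wedge) times a *source time course* (shared across
wedges within an area). Under these assumptions, identifying the areas
behind a VEP signal reduces to regressing observed topographies on the
areas' predicted topographies, and identifying their relative timing
reduces to fitting lags of a shared time course.

The stimulated field is an annulus (2.75-7.25 degrees eccentricity)
split into 16 wedges of 22.5 degrees polar angle, indexed clockwise
from the upper vertical meridian. Visual-field polar angle in (0, 180)
lies in the right hemifield and projects to left-hemisphere cortex.
Each wedge is tagged with its quadrant and its rank from the vertical
meridian (`vm_rank` 1 = adjacent to the vertical meridian, 4 = adjacent
to the horizontal meridian); the within-quadrant statistics are built
on this bookkeeping.

## Parametric cortical geometry

The atlas/MRI chain that normally produces predicted topographies
(surface reconstruction, retinotopy atlas fitting, boundary-element
head model) requires external anatomical data. It is replaced here by
a parametric stand-in that preserves the *geometry-driven logic*:

* Each area is a thin dipole ribbon per quadrant at cortical radius
  0.07 m near the occipital pole, with 25 dipoles per wedge sampled
  strictly inside the wedge's angular span.
* Moment directions live in the (medial, superior) plane of the source
  hemisphere, with the "superior" axis tilted 25 degrees posteriorly
  (the occipital banks curve around the pole). Lower-field moments
  mirror the vertical component of the upper-field track.
* **V1** rotates from a wall-like direction 50 degrees off medial at
  the vertical meridian to 80 degrees (near-sulcal, vertical) at the
  horizontal meridian, at x = 4-8 mm from the midline. The 50-degree
  wall angle is the smallest keeping mirrored upper/lower moments
  opposed (`cos 2*theta < 0`), which encodes the polarity inversion.
* **V2** starts V1-aligned on the border strip (a plateau over the
  first quarter of the quadrant), then folds to -50 degrees and
  continues to -80 degrees at the horizontal meridian — the opposite
  rotation sense to V1, ending polarity-reversed against V1. Its
  ribbon sits deeper and more lateral (x = 8-16 mm, 22-32 mm from the
  Calcarine level).
* **V3** holds a constant -90 degree (vertical, field-opposed) moment
  within each quadrant, deeper and more lateral still.

These parameters were chosen once so that the projected topographies
reproduce the qualitative structure the analysis depends on — V1
upper-ipsilateral/lower-contralateral laterality monotone in
`vm_rank`, the reversed and monotone-opposite pattern for V2,
near-midline V3, positive V1-V2 and negative V1-V3 stacked
correlations — and are exposed as `GeometryParams` for sensitivity
analyses. They are a caricature of occipital anatomy, not a fit to any
brain.

Dipoles project to the scalp through a single-shell homogeneous
conducting sphere (radius 0.09 m) using the classical Legendre-series
solution, truncated at 100 terms (the series converges geometrically
in dipole eccentricity, here <= 0.78; the centre-dipole closed form is
used as an exact cross-check in the tests). Conductivity is unity:
every downstream analysis z-scores or correlates topographies, so the
overall scale is immaterial — which is also why externally computed,
atlas-based topography tables (loadable from TSV) drop in without any
calibration. Wedge topographies are dipole-patch means, re-referenced
to the electrode average. Moment arrows carry the surface-negative
convention: the arrow head is the negative pole.

The 128-channel layout is a deterministic spherical-cap tessellation
(seven rings, populations 1/6/12/18/24/30/37, uniform azimuths starting
at the anterior midline, cap extending 115 degrees from the vertex).
It is mirror-symmetric about the sagittal plane, which makes the
left-right mirror tests exact; its `lateral_coord` is the x coordinate
scaled to [-1, +1].

## Stimulation protocols

* **Transient**: 200 trials per wedge, 50 ms flashes, 550 ms onset
  asynchrony, randomised order.
* **Multifocal**: 16 streams, each a cyclic shift (default 255 frames)
  of an order-12 maximal-length sequence (default polynomial
  x^12+x^6+x^4+x+1; taps are polynomial exponents). Pulses are
  off-to-on transitions (1024 per cycle, counting the wrap-around);
  keeping every 4th in temporal order leaves 256 per stream over
  54.6 s at 75 frames/s. The decimation phase is configurable. A
  diagnostic reports the maximum pairwise correlation among the kept
  indicator trains (~0.04 at zero lag) but no value is asserted: the
  decimated streams are only approximately orthogonal, which matters
  below.
* **Steady state**: square frame trains (2 on / 2 off = 18.75 Hz,
  5 on / 5 off = 7.5 Hz at 75 frames/s), six 5-s periods per wedge and
  frequency, with wedges 180 degrees apart paired across the two
  frequencies. CRT raster delay is `fraction-from-top x 11.5 ms`.

## Signal conditioning

The low-pass is a 77-tap Hann-windowed sinc at 512 Hz. The family has
a single free parameter (the nominal cutoff), which by default is
tuned by root-finding so that the stopband null nearest the transition
band falls exactly on 50 Hz, maximising mains rejection; the measured
3-dB corner of that design is 35.81 Hz. `measure_response` reports
gain in dB relative to DC (the corner convention), flooring magnitudes
at machine epsilon so exact nulls report large finite attenuations.
Filtering is delay-compensated by (n_taps-1)/2 samples, so the overall
operation is zero-phase and component latencies are preserved.

Low-frequency trends are removed by segmented linear detrending rather
than a high-pass filter (no causal-filter waveform distortion), with
segment lengths per protocol — 4 s transient, 5 s SSVEP, 0.5 s mfVEP —
and partition edges nudged to the nearest sample outside every epoch
window (overlapping windows are merged first, so one nudge always
lands outside all of them). Persistently noisy channels are found per
5-s partition (low-frequency SD after a 5 Hz low-pass > 20 uV, or
residual high-frequency SD > 10 uV), and runs of >= 7 flagged
partitions (bridging clean gaps of <= 2) are replaced by
inverse-distance interpolation of the four nearest clean neighbours.
Artifact rules: 20-ms-lag amplitude difference > 50 uV (pops); per 1-s
rectangular-window DFT, band-maximum ratios 0-3 Hz vs 3-7 Hz > 5
(drift) and 20-40 Hz vs 3-7 Hz > 2 (muscle); 200-ms moving average of
the differentiated vertical EOG difference > 1 uV (blinks); gaze
displacement > 0.2 degrees per 10 ms (saccades). Trials are rejected
when a blink or saccade intersects [-50, +200] ms around onset.

## Signal derivation

Transient and multifocal responses are -100 to 400 ms stimulus-locked
averages per wedge; C1 topographies are the 70-80 ms window mean. The
multifocal waveforms can instead be obtained by least-squares
deconvolution against the lagged pulse design. The default lag grid is
every sample; a coarser grid at the 75 Hz stimulus frame period
(512/75 samples, interpolated back) is provided because pulse timing
carries no sub-frame information and the sample-resolution design is
nearly singular at sub-frame lags, which inflates estimation noise.

SSVEP analysis discards the first 500 ms of each flicker train, takes
one 4-s epoch, and keeps the DFT coefficient at the exact flicker bin
(integer cycles in 4 s; leakage-free, so no taper is used). The
amplitude convention is `A cos(2 pi f t + phi) -> A e^{i phi}`, with
the phase referenced to the flicker-train onset; coefficients average
across epochs as complex numbers so polarity-opposed oscillations
cancel. The principal phase axis is the leading eigenvector of the
(Re, Im) second-moment matrix over all electrodes and wedges (a line
through the origin; no centering), estimated at the grand-average
level only. Its polarity is anchored to the C1 convention: the
dominant focus of the upper-field wedges nearest the horizontal
meridian (`vm_rank` 4) projects negative. Flipping the anchor flips
all projections jointly and cannot change any correlation magnitude.

## Topographic statistics

Correlations treat electrodes as observations, per wedge and stacked
(16 x 128 = 2048 pairs). Permutation nulls shuffle the predicted set's
wedge labels, freely or within quadrants; because the stacked mean and
SD are permutation-invariant, each draw reduces to a sum of 16
precomputed block cross-products, so 10^6 draws take well under a
second. Draws are sampled with replacement from the permutation group;
exact enumeration of the within-quadrant group ((n/4)!^4) is available.
p-values are two-sided with the add-one correction. The Fig-4C-style
contrast between two nulls sign-flips any negative-centred null (so
differences live on the absolute-correlation scale) and builds a
percentile CI from paired bootstrap resamples of the two null samples
— the bootstrap construction is this package's choice, as the original
procedure is underdetermined.

The laterality index first resolves the field-to-polarity mapping from
the data (the sign of the largest-|value| electrode of the mean
upper-field topography), then takes the amplitude-weighted centre of
gravity of `lateral_coord` over dominant-polarity electrodes, signed
so +1 = all amplitude on the most lateral ipsilateral electrode. It is
scale invariant and exactly antisymmetric under left-right mirroring
of a mirror-symmetric layout.

## Area regressions

Stacked designs z-score the outcome and every regressor over the 2048
observations and fit by OLS without intercept; R^2 = 1 - RSS/TSS and
BIC = n ln(RSS/n) + k ln n with k counting regressors — the standard
choices for standardised designs, stated here because they fix the
scale of the reported tables. All non-empty area subsets are
enumerated (7 models for three areas, 15 when an MT set is loaded) and
the lowest BIC flagged. Time-resolved fits slide a 10-ms window in
5-ms steps over -100 to 400 ms (101 windows), z-scoring the outcome
with moments pooled over the whole epoch so betas are comparable
across windows; bootstrap SEs resample the 2048 stacked observations
with replacement, implemented as multinomial row weights (1000
resamples by default). Beta dominance reports |beta_V1| - |beta_other|
alongside beta_V1.

## Shared-lag sinusoidal SSVEP model

Each complex coefficient is expanded into one single-cycle cosine
snippet (round(fs/f) samples: 68 and 27 at 512 Hz, which puts 71.6% of
the stacked samples in the 7.5 Hz block); snippets of both frequencies
stack into one outcome vector. Each area contributes one regressor per
frequency — predicted amplitude times a cosine at baseline phase
phi_f minus 2 pi f lag_a, zero-filled in the other frequency's rows —
and everything is z-scored. V1's lag is fixed at 0; V2 and V3 lags
share across frequencies.

The grid over (phi_7.5, phi_18.75, lag_V2, lag_V3) is scanned without
ever rebuilding the design: every regressor is a cosine/sine
combination of 12 fixed basis columns, so each grid point costs one
6x6 solve derived from a precomputed 12x12 Gram matrix. The default
scan is coarse (4 ms lags over +/-66 ms, 8 phases per cycle) followed
by local refinement at the sample period around the best few distinct
coarse lag basins — refining several basins matters because at low SNR
a half-period alias of the 18.75 Hz component can top the coarse scan.
An exhaustive full-resolution mode exists. Models with any
non-positive fitted magnitude are inadmissible (phase flips make signs
redundant); the best admissible R^2 wins, and the top-1% admissible
set is retained for parameter-distribution summaries. Phase-grid
resolution is one sample of the respective cycle, matching the lag
resolution.

Per-wedge SSVEP phase summaries use axial statistics (angles doubled,
magnitude-squared weights) because dipolar topographies contain
antiphase foci that would cancel an ordinary circular mean.

## Synthetic data: what it emulates, and what not

Recordings are 128 channels at 512 Hz built as per-area topography
times time-course sums plus noise. Defaults encode the study
conditions: 200 transient trials per wedge at 550 ms asynchrony;
multifocal streams from the decimated order-12 sequence; six 5-s
flicker periods per wedge and frequency with opposite-wedge pairing
and an onset transient in the first 500 ms. Evoked kernels are
Gabor-windowed biphasic lobes (sigma 15 ms, 10 Hz carrier) with the
analytic envelope-weighted carrier mean subtracted so the kernel
integrates to zero — real evoked responses carry no net DC, and a
nonzero kernel integral would give rapid overlapping protocols a
baseline shift no real recording shows. The V1 kernel peaks at 75 ms
(the C1 frame); V2 and V3 kernels lag by 35 and 55 ms; steady-state
lags default to 20 and 24 ms. Evoked mixing weights default to the
dominant-V1 pattern (0.7 / -0.05 / -0.15); recovery tests that need
every generating area detectable at their stated SNR use
(0.7 / 0.2 / -0.15) instead, since a |weight| ~ 0.05 sits below the
BIC detection threshold at 2048 observations and its recovery rate
would measure identifiability, not correctness. Noise is Gaussian with
a 1/f power spectrum, spatially mixed across electrodes with a
Gaussian kernel (0.5 chord-length), scaled to a target per-channel SD
— an invented but EEG-plausible model; parameters are exposed.

Not emulated: subject-to-subject anatomical variability (grand-average
level only), realistic ocular artifact waveforms (the detectors are
tested with injected templates), stimulus rendering and luminance, and
non-sinusoidal SSVEP harmonics. Passing recovery tests therefore show
the *estimators* are correct under the model's own assumptions; they
cannot certify performance on real data whose noise violates them.

## Numerical choices and degenerate inputs

Zero-variance topographies, all-zero spectra, empty wedges, constant
voxel cubes, non-primitive feedback taps, out-of-sphere dipoles and
degenerate (duplicate) pulse streams raise errors naming the offending
object. Collinearity is detected via the Gram condition number (OLS)
or a failed Cholesky factorisation (deconvolution). The permutation
p-value is never 0 by construction. Exact DFT-bin arithmetic is
enforced for SSVEP frequencies (a non-integer cycle count in the epoch
raises). Lag and phase grids are deduplicated after clipping so
degenerate (zero-width) ranges stay cheap.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at reduced but structure-preserving sizes
chosen as the package's own test conditions: transient recovery uses
2-20 trials per wedge (noise-free identities are exact at any trial
count); the multifocal method comparison uses one to ten full 54.6-s
runs; steady-state recovery uses one to six 5-s periods per condition;
permutation checks use 10^3-10^5 draws (the draw loop is O(16) per
permutation, so these bounds are convenience, not approximation); the
lag-grid recovery sweep uses 20 seeded datasets at the noise level
giving best-model R^2 near 0.4.

## Known limitations

* The parametric geometry reproduces qualitative topography structure;
  predicted-topography *magnitudes* are defined only up to scale, and
  inter-area correlation magnitudes (e.g. V1-V2 stacked r ~ 0.1) are
  smaller than atlas-based values, making cross-area confusions milder
  than in real data.
* The epoch-averaged multifocal waveform retains deterministic overlap
  bias from the decimated concurrent streams (the same structure that
  produces pre-stimulus explained variance in multifocal fits); the
  regression method removes it. Their agreement on synthetic sessions
  saturates near r = 0.92-0.97 depending on averaging, so the two
  derivations should be treated as close but not interchangeable at
  single-session scale.
* The 77-tap Hann-sinc family cannot simultaneously realise a 35.3 Hz
  measured corner and 83.5 dB attenuation at exactly 50 Hz; the
  package's default takes the mains-null design (corner 35.81 Hz,
  attenuation limited only by measurement precision) and documents the
  corner-matched alternative (~50.8 dB at 50 Hz).
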