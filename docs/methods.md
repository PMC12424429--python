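# Methods

## Data model and conventions

The pipeline starts from tidy localization tables (cell, channel,
trajectory, frame, x/y in μm, intensity) produced by any SPT tracker; raw
image processing and track linking are out of scope. Coordinates are stored
in μm and confinement zone sizes reported in nm; frames are 0-based; the
frame interval defaults to δt = 1/30 s (video rate, "33-ms resolution";
5 frames = 166.7 ms). Frame gaps split a trajectory into separately-analyzed
pieces rather than being interpolated, because the confinement detector
assumes consecutive frames; how (or whether) broken tracks were re-linked in
the original analyses is not documented, so gap-splitting is this package's
convention. Quantitative analyses use trajectories of ≥ 10 frames
(inclusive); the recruitment module exposes the comparison operator because
the source protocols alternate between "over 10 frames" and "≥ 10 frames".

Channel models carry the measured per-axis localization precision
(14.0 nm green / 18.7 nm red) and photobleaching lifetime (10.4 s / 8.1 s).
The quoted precisions could be read as per-axis or radial SDs; they are
treated as per-axis here, which is the more conservative (noisier) reading
and directly enters the zone-size correction and the simulator.

## D_200ms estimation

MSD(nδt) is the mean over the N−n overlapping windows of a trajectory's
squared lag-n displacements. (A common alternative normalization counts
"partial trajectories" as N−n+1; only the N−n displacement count yields an
unbiased slope, and it is what this package uses.) D_200ms is slope/4 of an
unweighted OLS line with intercept through the MSD values at lags 5, 6 and
7 (167/200/233 ms at video rate); the lags are frame counts, and a warning
is raised when δt deviates from video rate by more than 5%. By default the
MSD uses all overlapping windows of the full trajectory, which maximizes
precision; `use_first_frames=10` reproduces a fixed-330-ms evaluation
literally.

Negative D_200ms estimates (common for short noisy tracks — the 3-point
slope at N = 10 has an SD comparable to D itself) are retained, not
clipped, so that percentile calibration on a reference population stays
well defined. Mobility is immobile iff D_200ms < threshold (strict).
The threshold can be recalibrated as the 95th percentile
(linear-interpolation convention) of D_200ms over an immobilized reference
population.

**Estimator noise matters.** The per-trajectory D_200ms distribution is
tight only for long tracks. At N = 10 the median is biased ~40% low and a
quarter of truly mobile tracks fit a negative slope; at N ≥ 50 the median
recovers D within a few percent. Parameter-recovery validations therefore
use bleach-limited track lengths (see below) rather than fixed 10-frame
tracks, matching how the imaging actually truncates trajectories.

## Transient-trapping detection

An event is ≥ 5 consecutive localizations confined within a 50-nm radius of
the event centroid (a 100-nm-diameter zone). The published analyses cite a
confinement-detection method plus unpublished modifications without
pseudocode, so the detector here is one deterministic instantiation, chosen
for testability:

1. anchor a candidate window at a frame and grow it frame by frame,
   requiring after each growth step that *every* member lie within the
   radius of the running centroid;
2. verify all members against the final centroid, trimming trailing frames
   that violate it (a provable no-op under rule 1, retained as a guard);
3. accept if ≥ 5 frames remain; resume scanning at the frame after the
   accepted event (events never overlap, earliest-start tie-breaking).

A single excursion frame terminates an event; there is no excursion
tolerance. With combined per-axis scatter √(conf² + σ²) ≈ 17 nm, the
excursion probability is ~1.5% per frame, so a small fraction of long
events is split into fragments; the simulator quantifies this (it costs
~5% of the mean event duration under the activated-KRAS-like conditions).
Event duration is (frame count) × δt. Zone size is the radial RMS distance
of event positions from the centroid ("SD of the distances"), corrected for
localization precision by quadrature subtraction, corrected_sd =
√(max(raw_sd² − 2σ², 0)) — equivalent to a Gaussian-model correction for
isotropic noise — and the zone area is reported as corrected_sd² in
multiples of π nm². Per-cell summaries divide total event time (temporal
fraction) and event count (frequency) by the cell's total tracked time over
length-filtered trajectories.

## Colocalization

Channels are assumed registered and synchronously acquired. Pair distances
between channels are accumulated per frame into 50-nm annuli out to 500 nm
and divided by annulus area π(r₂²−r₁²), making the complete-spatial-
randomness (CSR) null flat; no edge correction is applied, so a warning is
raised when the ROI is small relative to the outermost annulus. The
colocalization index is the 0–50 nm pair density over the 400–500 nm pair
density — exactly 1 under CSR. Whether the original index used raw or
area-normalized pair counts is not stated; normalized is the default here
(it is geometry-independent), and a raw-count mode is provided. Frame-wise
colocalization uses the 240-nm criterion, under which truly bound pairs
with 14.0/18.7-nm channel noises are scored colocalized in ≥ 99% of frames.

## Recruitment

Per cell, spot intensities (minus a per-spot scalar background) of
trajectories passing the persistence filter are summed; ratios are taken to
the same cell's value at the reference time point (1 min post-stimulation
by convention) and averaged across cells with SEM. The PS-probe spot
density is count / (whole-cell intensity × observation area).

## Synthetic trajectories

The generator emulates the imaging conditions: a two-state continuous-time
Markov chain with exponential trap/free dwells (occupancy =
τ_trap/(τ_trap+τ_free); the constructor accepts either parameterization),
Brownian free motion with per-axis step SD √(2Dδt), i.i.d. Gaussian
confinement (per-axis SD `trap_conf_sd`, default 10 nm) about a trap center
fixed per event, per-axis localization noise on every position, and
geometric photobleach truncation with mean `bleach_lifetime`/δt frames
capped at a 300-frame (10-s) movie. State switches occur at frame
boundaries (dwells rounded to whole frames). The trap center sits one free
step beyond the last free-state localization — the molecule diffuses into
the trap during the switching interval — otherwise the boundary free frame
coincides with the center and the detector systematically absorbs it.
Trapped-state dynamics are i.i.d. scatter rather than an
Ornstein–Uhlenbeck process; OU dynamics are a documented extension point.
Experiments draw per-cell child seeds from one seed sequence, so results
are bit-exact reproducible from (preset, seed) and cells are independent.

Shipped presets reverse-engineer generative parameters from published
summary statistics (free D from the mobile median D_200ms, trap dwell mean
from the mean detected duration minus the threshold time, occupancy from
the detected temporal fraction via the length-bias factor below). They are
for validation by parameter recovery, not biological claims.

### Truncation oracles

For exponential dwells with mean τ and threshold time T = 5δt,
memorylessness gives the mean of detectable dwells as T + τ and the
fraction of trapped *time* lying in detectable dwells as e^(−T/τ)(1 + T/τ)
(length-biased truncation). `calibrate_occupancy` inverts the latter to
build presets whose detected temporal fraction should match a target.

Two systematic gaps between these continuous-time oracles and the
frame-quantized process are worth knowing:

* **Half-frame duration deficit.** Any frame-boundary quantization of an
  exponential dwell has a geometric tail with ratio e^(−δt/τ), so the mean
  detected duration is (m−1)δt + δt/(1−e^(−δt/τ)) ≈ (T − δt/2) + τ rather
  than T + τ — about 5% short at τ ≈ 170 ms. Together with event
  splitting this puts the recovered mean duration ~10% below the
  continuous oracle; the duration-recovery validation sits at the edge of
  its tolerance for this reason, with long movies and no bleach truncation
  used there to keep end-clipping out of the measurement.
* **Length-bias surplus.** The same quantization makes the detectable-time
  factor behave like the continuous factor evaluated at T − δt/2 (a few
  percent high; larger for short τ). Calibrated temporal-fraction
  recoveries therefore land slightly above their targets, further inflated
  at slow diffusion and high occupancy by bridging of single-frame free
  interludes (at D = 0.1 μm²/s a free step stays within the 50-nm radius
  ~17% of the time).

## Statistics layer

Welch's t (Welch–Satterthwaite dof), Mann-Whitney U (exact enumeration for
n ≤ 8 without ties, normal approximation with tie correction otherwise) and
Spearman's ρ are delegated to scipy.stats; significance stars use strict
thresholds 0.05/m, 0.01/m, 0.001/m (m = 3 gives the 0.017/0.003/0.0003
convention at printed rounding). Box summaries use type-7
(linear-interpolation) quartiles — no convention was stated — with whiskers
at the most extreme observations within 1.5×IQR of the box.
Photobleaching lifetimes are fitted by the exponential MLE (sample mean),
with a left-truncation correction (mean − T) for detection-thresholded
dwells.

## Problem sizes used in validation

The recovery suite simulates 20 cells × 200 trajectories for
temporal-fraction recoveries, ~25,000–35,000 events (six cells of 90
trajectories × 3,000 frames, no bleaching) for the duration recovery,
5,000+ bleach-limited tracks for the median-D recovery, and a 10,000-track
mixture for immobile-fraction recovery — sizes at which Monte-Carlo error
is small against each tolerance while the full suite runs in minutes on
one core.

## What passing (and failing) the synthetic validations shows

The generator reproduces the statistical structure the analysis assumes —
two-state switching, Gaussian confinement, static localization noise,
exponential bleaching — but not every feature of real data: no dynamic
(motion-blur) localization error, no anomalous sub-diffusion or hop
diffusion, no tracker linking errors or blinking-induced track breaks, no
drift, and trap zones that are pure Gaussian wells rather than structured
nanodomains. Recoveries here validate the estimators against their own
model assumptions; they do not certify accuracy on data violating them.

Two known limitations surfaced by the validations themselves:

* The immobile/mobile classifier has a track-length-dependent false-positive
  rate (~11% for mobile tracks shorter than ~30 frames, ~0.8% overall under
  bleach-limited lengths), so a recovered immobile fraction overshoots the
  true mixture weight by roughly that amount — e.g. a 3.2% mixture reads
  as ~3.8%. Published immobile fractions produced by the same estimator
  carry the same kind of offset.
* The 95th-percentile threshold calibrated on *synthetic* stationary
  emitters (pure 14-nm localization noise, 10-frame tracks) is
  ~0.003 μm²/s, a factor ~3 below the 0.009 μm²/s obtained on real
  glass-immobilized references — real reference molecules evidently carry
  residual motion (wobble, drift, dead-cell membrane fluctuations) beyond
  pure localization noise. The printed threshold is kept as the package
  default; the calibration routine is provided for users with their own
  reference data.
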