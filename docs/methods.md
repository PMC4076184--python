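# Methods

This note documents the models, conventions and numerical choices behind
`boldcaps`, and what its synthetic benchmarks do and do not demonstrate.

## The point-process model of seed co-activation

A seed-correlation map is a session-long average and hides the fact that
the seed co-activates with *different* whole-brain configurations at
different moments. The CAP approach makes that explicit: the standardized
seed signal is thresholded (default +1 SD, strict `>`), the whole-brain
z-maps at supra-threshold frames are collected, and k-means groups them
into K spatial states. Averaging each cluster gives the CAPs, and the
occupancy-weighted mean of the CAPs reproduces the grand mean of the
selected frames exactly — a linear-algebra identity the implementation
asserts to 1e-8, independent of how well the clustering fits.

Two clustering modes exist because two questions exist. *Free* k-means
(`CapKMeans.fit`, k-means++ with 10 restarts, best of restarts by
within-cluster sum of squares, fixed `random_state`) answers "what states
exist in this reference data". *Fixed-centroid assignment*
(`CapKMeans.predict`, nearest centroid under the same metric, ties to the
lowest index, centroids never updated) answers "how does each state
change across conditions" — cap index j means the same thing in every
condition because the centroids come from one reference fit and are
immutable (hash-checked in the pipeline manifest). The distance metric
centers and unit-normalizes each frame before Euclidean k-means, which
ranks neighbors identically to 1 − Pearson correlation; frames that are
numerically flat (centered norm at rounding level relative to the frame's
magnitude) map to the zero vector rather than a spurious direction.

Caps are averaged from the *standardized but not per-frame-normalized*
frames, so cap amplitude keeps its meaning in units of temporal SD.

## Preprocessing conventions

Stage order is detrend → bandpass → nuisance regression → smoothing →
standardization. The order is a package convention (upstream tools do not
fix one): regressing after filtering avoids re-introducing out-of-band
variance through the regressors, and smoothing before z-scoring matches
the usual volumetric workflow. Each stage is independently callable.

* **Bandpass** 0.005–0.1 Hz, Butterworth order 2 per edge, applied
  forward-backward (`sosfiltfilt`). Zero phase matters here: the point
  process keys on event *timing*, and a causal filter would shift peaks
  by a frame or more at TR = 2.46 s. The effective stop-band attenuation
  (squared single-pass response) is ≤ 0.01 at one octave beyond the band.
* **Detrending** projects onto an orthonormalized {1, t, t²} basis;
  residuals are orthogonal to the basis to rounding precision.
* **Nuisance regression** always includes an intercept, validates the
  design for collinearity (QR with pivoting names the offending columns),
  and projects with a pseudoinverse. WM/CSF regressors are ROI means from
  caller-supplied masks — synthetic grids have no tissue segmentation, so
  the default pipeline uses motion parameters only.
* **Smoothing** uses `scipy.ndimage.gaussian_filter` with reflective
  boundaries (no edge dimming on small grids),
  σ = FWHM/(2√(2 ln 2)) per axis in voxel units; out-of-mask voxels are
  re-zeroed afterwards, so all stages are mask-respecting.
* **Standardization** uses the sample SD (ddof = 1) — fixed for
  bit-reproducibility. Constant voxels become zero with a counted
  warning, never NaN.

## Motion QC

FD follows the sum-of-absolute-differentials convention with rotations
converted to arc length on a 50 mm sphere; DVARS is the RMS frame
difference over in-mask voxels as a percentage of the grand-mean
intensity, computed on data *before* standardization ("% BOLD" is
meaningless after per-voxel z-scoring). Both are zero at frame 0. The
default censoring rule requires **both** indices above threshold
(0.5 mm / 0.5 %); the either-exceeds rule used elsewhere in the
scrubbing literature is available as `rule="or"` so the discrepancy is
explicit rather than hidden. Censoring is applied before frame selection
by default, but selection fractions are reported against both the total
and the kept frame count, since post-hoc censoring is equally defensible.

## Group statistics

Subjects are random effects: the unit of analysis is the per-subject,
per-condition mean map of the frames assigned to one cap. The
consciousness contrast `[1.5, −0.5, −1.5, 0.5]` (wakefulness, sedation,
unconsciousness, recovery; recovery down-weighted because sedative plasma
levels have not fully cleared) is collapsed to a single within-subject
value per voxel and tested with a one-sample one-sided t. Collapsing the
contrast within subject sidesteps the sphericity assumptions a
repeated-measures ANOVA with non-sphericity correction would need, while
testing the same one-sided hypothesis; this is a deliberate divergence
from ANOVA-based implementations. Zero-variance voxels return documented
sentinels (±∞ t with p ∈ {0, 1}; all-zero gives t = 0, p = 0.5).
Multiple comparisons use Benjamini–Hochberg step-up FDR
(via `statsmodels`), cross-checked in the tests against a literal
step-up enumeration on all short p-vectors.

Seed-correlation maps and sliding-window correlation maps (window ≥ 3
frames) are provided as the static and dynamic baselines the CAP
decomposition is compared against.

## The synthetic cohort generator

The generator emulates the acquisition this analysis was designed for:
18 subjects × 4 conditions × 197 volumes at TR = 2.46 s on a 3 mm grid
(default 20 × 24 × 20 with an ellipsoidal brain mask). Each session is

    baseline + amplitude · Σ_j gain[c, j] · pattern_j(x) · (e_j ∗ h)(t)
    + drift(x, t) + noise(x, t),

with per-frame Bernoulli event trains `e_j` (rate 0.15, pattern identity
drawn from the condition's gain-weighted categorical), the double-gamma
HRF `h` sampled at the TR and renormalized to unit peak (so a noiseless
single event reproduces `amplitude · gain · pattern` exactly at the peak
lag), per-voxel linear+quadratic drift, and a 2 × 2 × 2-voxel seed cube
set to 1 in every pattern so each event raises the seed.

Scales are mutually realistic in percent-signal units: baseline
1000 a.u., thermal + physiological noise SD 2.5 (0.25 %), event amplitude
12 (1.2 %), drift 2. Planted patterns are plateau-profiled parcels
(Gaussian blobs, σ = 2.2 voxels, raised to the 0.4 power) accepted only
if pairwise spatial correlation stays below 0.5. Noise is a mixture of
i.i.d. and spatially smooth components (70 % of variance at σ = 2 voxels)
— without the structured component, 8 mm smoothing annihilates i.i.d.
noise and per-voxel z-scoring then saturates every voxel the smoothed
signal touches, turning frames into support indicators; real BOLD noise
is dominated by spatially structured physiological fluctuations, and
modeling that keeps z-maps proportional to the planted amplitude. For the
same reason pattern-recovery correlations are *not* monotone in SNR: in
the exact zero-noise limit the z-scored frame degenerates to a support
map and correlations with the amplitude patterns drop. Recovery
benchmarks therefore run at the default noise level; the zero-noise
planted-signal identity is asserted on raw (unstandardized) data, where
it holds exactly.

Motion spikes (rate 0.03, between the 1–8 % per-state censored fractions
reported for comparable acquisitions) combine a sustained 1 mm
translation offset — an FD spike at the onset frame only — with a
one-frame ±1 % global intensity blip — a DVARS spike. Under the joint
AND rule exactly the planted frames are censored; two planted spikes on
adjacent frames with same-sign blips can mask each other's DVARS
excursion, which keeps the censored fraction within binomial error of
the plant rate rather than exactly equal.

What the synthetic benchmarks do **not** show: performance under real
physiological confounds (cardiac/respiratory aliasing), susceptibility
artifacts, imperfect registration, HRF variability across regions, or
non-Bernoulli event dynamics. Passing them demonstrates that the
machinery is correct and well calibrated, not that the biological
conclusions of any particular study are reproduced.

## Problem sizes of the shipped benchmarks

The test suite and the acceptance script use scaled cohorts chosen as the
smallest sizes at which each property is statistically comfortable: 8
reference subjects and 4 study subjects (197 frames each) for clustering
recovery and fixed-centroid comparison; 18 × 197 null series for the
selection-fraction check; 200 replicates of 18-subject × 400-voxel maps
for contrast calibration. The full 18-subject generator defaults remain
available for larger experiments.

## Known limitations and extension points

* HRF deconvolution before frame selection is an extension point, not
  implemented.
* Model selection over K is out of scope; K = 8 follows the analysis
  convention this package mirrors.
* The MNI seed default (0, −53, 26) is logged at use; published
  coordinates for this seed occasionally appear with the y-sign dropped,
  and the value is fully configurable.
* Cluster-extent or random-field inference is not provided; significance
  is voxelwise under FDR.
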