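# Methods

This note documents the models, parameters and numerical choices behind
`reinstate`, in the spirit of a simulator/statistics package's methods
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Design being emulated

A three-phase video-memory study: 21 subjects; 24 unfamiliar silent videos of
29–48 s (mean 38 s); encoding (`Enc`) and immediate cued retrieval (`ImRet`)
split over two Day-1 runs of 12 videos; delayed retrieval of all 24 videos in
one Day-8 run (`DelRet`). Retrieval trials start with a 2 s title+screenshot
cue and are self-paced within a (20, 55) s window (modeled as a truncated
normal, mean 35 s, SD 8 s); trials are separated by a 12 s fixation ISI and
followed by a 1–6 vividness rating. EPI sampling is TR = 2.62 s on a 3 mm
isotropic grid. After the Day-8 scan, free recall of each video is scored
detail-by-detail with marks of 0 / 0.5 / 1 whose uncapped sum is the video's
detail score (group mean ≈ 11.5, SD ≈ 2.7).

All synthetic data live on a single common grid; the native→template
normalization step of a real study is deliberately not reproduced (it is a
no-op for data generated already aligned), and group maps stay at the 3 mm
analysis resolution rather than being resampled to 2 mm.

## 2. Synthetic pattern model

Patterns are generated directly at the level the RSA consumes: one
trial × voxel matrix per subject and phase (a stand-in for per-trial GLM
t-maps; the time-series generator below produces actual series when the GLM
itself is under test). Within an effect region, a trial pattern for video v
is

    x = √c · common + √ρ_v · latent_v + √(1 − c − ρ_v) · ε

with all components unit-variance Gaussian: `common` is shared by every
trial of the subject in the region (producing a nonzero different-video
correlation c, as real data show); `latent_v` is the video's pattern, shared
across phases within subject and, with fraction `shared_fraction` of its
variance, across subjects; ε is trial noise. Cross-phase correlations are
then exactly c (different video) and c + ρ_v (same video), so a requested
Fisher-z gap δ is planted by solving

    c = tanh(base_z_diff),  ρ_v = tanh(base_z_diff + δ + β·s_v) − c

where s_v is the subject's mean-centered (relative) memory score for video v
and β (`behavior_coupling`, z-units per detail point) couples reinstatement
strength to behavior. Configurations implying c + ρ ≥ 1 are rejected.
Outside effect regions, patterns are pure N(0, 1) noise. The expectation of
a *sample* correlation over k voxels is slightly below the population value
(order ρ/k); with k ≈ 123-voxel searchlights and k ≈ 500+ ROIs this bias is
far below the Monte-Carlo tolerances used in the tests.

The calibration is verified empirically in the suite: over 100 replicate
seeds, a requested δ = 0.3 in a ~2000-voxel region is recovered as an
ROI-level same-minus-different Fisher-z gap within 20%.

Default effect magnitudes in `pipeline.default_config` emulate the scale of
posterior-midline reinstatement reported for this kind of design — a
different-video baseline z ≈ 0.103 and same-video z ≈ 0.136 (δ ≈ 0.033) —
with β = 0.02 and shared fraction 0.4. These are realism anchors for the
generator, not reproduction claims.

### Behavior

Detail scores are N(11.5, 2.7²) rounded to 0.5 steps and floored at 0;
relative scores subtract each video's across-subject mean. Vividness has a
subject-level ImRet baseline N(4.2, 0.4²), a within-subject coupling to the
score profile (coefficient 0.26, chosen to put per-subject vividness–score
correlations in the 0.5–0.6 range so that a clear majority — not all — of
21 subjects are individually significant), a subject-level Day-8 drop
N(0.7, 0.4²), and per-trial jitter, clipped to [1, 6]. The drop SD of 0.4
makes the group paired-t for the vividness drop land in the ~7–8 range at
n = 21 rather than being arbitrarily large.

### Time series

BOLD-like runs are built by convolving each trial's boxcar with the glover
double-gamma HRF (nilearn's `compute_regressor`, 16 oversampling bins per
TR) and multiplying by the trial's spatial pattern, then adding: a global
drift (standardized random walk) hitting every voxel, six smooth
motion-correlate series with random per-voxel couplings, and white noise of
SD `noise_sd`. Out-of-brain voxels serve as the white-matter compartment for
the drift regressor. Trial onsets are expressed relative to the retained
series; the first five volumes are discard padding. No slice-timing offsets
or autocorrelated noise are simulated.

## 3. First-level GLM

One regressor of interest per trial (variable duration), one 2 s regressor
per retrieval cue, and nuisance columns: rating events (default 4 s at each
retrieval offset; the parameterization of the rating regressor is a config
knob since designs differ), six motion series, the global white-matter drift
(mean over WM voxels of each voxel's temporally z-scored series — used
instead of high-pass filtering), and an intercept. This yields 36 interest
columns per Day-1 run (12 Enc + 12 ImRet + 12 cues) and 48 for the Day-8
run. Fitting is plain OLS per voxel with t = β/SE and residual df =
volumes − columns; no AR(1) whitening (per-trial t-maps enter the analysis
only relationally, through correlations, so prewhitening would not change
the RSA contrasts materially — a deliberate simplification). Rank-deficient
designs raise an error naming the collinear columns. Voxels with zero
residual variance get flagged ±inf rather than raising, and exactly-zero
signal with zero noise yields t = 0; the GLM recovery tests therefore use a
negligible noise SD (0.01 against unit signal amplitude) instead of exactly
zero, which is also the numerically well-posed version of a "noiseless"
recovery check.

The cue-control variant `exclude_first_12s` starts each retrieval trial's
interest boxcar 12 s after onset and models the excluded windows with a
single shared no-interest column (the alternative — simply omitting the
window — is available by building the design from an edited trial table;
modeling it was preferred so cue-evoked variance is absorbed, not smeared
into residuals).

## 4. Searchlight RSA

Neighborhoods are Euclidean balls of radius 3 in voxel-index units (123
voxels when unclipped; ties at exactly the radius included; the 0.6 mm slice
gap of the emulated acquisition is ignored, i.e. distances are isotropic).
Centers whose in-mask neighborhood has fewer than `min_voxels = 10` voxels
produce NaN — a floor that prevents degenerate correlations at mask edges.
Correlations use only in-mask sphere voxels. A pattern with zero variance
within a neighborhood contributes r = 0 (with an aggregated log count)
rather than NaN, keeping maps defined.

The statistic is the weighted sum of Fisher-z correlations over
nonzero-weight pairs. Same-vs-different weights are normalized to
±1/N_same, ∓1/N_diff so the statistic reads as mean(same z) − mean(diff z);
an unnormalized "summed difference" mode (+1 per same pair) differs by the
constant factor N_same, which cannot change one-sample group inference — the
mean form was chosen for interpretability. Fisher z clips |r| at 1 − 1e−7 to
stay finite at degenerate self-correlations.

Implementation: all neighborhood sums (per-trial first/second moments and
per-pair cross-products) are accumulated by one sparse neighborhood-matrix
multiply, making a 21-subject, 6.6k-voxel, 288-pair searchlight run in
seconds. The engine is verified voxel-for-voxel (atol 1e−10) against a
naive double-loop oracle for all three phase pairs and both weight kinds.

ROI RSA treats all ROI voxels as one pattern and returns the same/different
averages separately (same-vs-different) or the weighted sum (weighted kind).
The ROI different-video averages honor the same Day-1 between-run exclusion
as the searchlight weight matrix, for consistency between the two readouts.

## 5. Inter-subject RSA

Patterns are smoothed with a 6 mm FWHM Gaussian kernel, renormalized within
the mask (the masked volume and the mask are both smoothed and their ratio
taken) so edge voxels are weighted averages of in-mask neighbors rather than
being diluted toward zero. Each subject's phase-A patterns are then
correlated, with the standard searchlight machinery, against the voxelwise
leave-one-out average of all other subjects' phase-B patterns for the same
video. The same-vs-different weighting is reused for the inter-subject maps
(a config switch allows same-video-only weighting); smoothing precedes
averaging. Note the subject maps are weakly dependent (each subject
contributes 1/(n−1) of every other subject's reference average); the
sign-flip group test treats them as exchangeable, and the suite verifies
empirically that its false-positive rate stays at the nominal level under a
fully unshared null.

## 6. Group inference

Voxelwise one-sample t (df = n−1) or paired t on subject maps. Cluster-
extent FWE control replaces parametric random-field correction with a
**sign-flip permutation**: under the null each subject map is symmetric
around zero, so flipping signs of whole maps is exact; the null distribution
of the maximum supra-threshold cluster size (cluster-defining one-tailed
p < .001 by default, two-tailed available for directionless paired
comparisons; 18-connectivity labeling, 6/26 selectable) yields corrected
cluster p values. All 2ⁿ flips are enumerated when 2ⁿ ≤ `n_permutations`,
otherwise seeded random draws with the identity included. An ROI argument
restricts thresholding and maxima (small-volume correction). The suite
calibrates this machinery directly: across 200 replicate null studies the
family-wise false-positive fraction lies within the binomial 95% CI of 0.05.

The 2×3 repeated-measures interaction (correlation type × phase pair) on ROI
Fisher-z values is computed via `pingouin.rm_anova` and cross-checked in the
tests against a direct sums-of-squares computation; df are derived from the
data's own dimensions (df2 = 2(n−1)).

## 7. Problem sizes used in the test suite

Monte-Carlo experiments run at desk scale, chosen once as a balance between
statistical resolution and a single-CPU run of the suite: type-I calibration
uses 200 replicate studies of 10 subjects on a 12³ grid with 1000
permutations; effect recovery uses 50 seeds of 21 subjects on a 16³ grid
with a 2028-voxel effect region; weighted-RSA power/null use 40 seeds each;
inter-subject specificity uses 25 power and 35 null seeds on a 12³ grid.
Binomial acceptance bands follow from these counts at the nominal rates.
The default full-study configuration uses a 24×28×24 grid with an
ellipsoidal ~6.6k-voxel brain mask.

## 8. What passing tests do and do not show

The generator produces Gaussian, spatially-white (apart from planted
structure and optional smoothing), motion- and physiology-free data on a
common grid. Passing tests therefore demonstrate the *correctness and
calibration of the analysis machinery* — not robustness to realignment
error, susceptibility dropout, autocorrelated or heavy-tailed noise,
imperfect normalization, or scorer disagreement in the behavioral data.
Anatomical labeling of clusters, DICOM/surface formats, and preprocessing
(realignment, slice-time correction, coregistration) are out of scope.
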