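# Methods

## The contraction waveform

Every synthetic clip is driven by a scalar fractional shortening d(t) ∈
[0, amplitude].  Each beat rises from its onset as a raised cosine,
d(s) = A/2 · (1 − cos(π s / t_tp)) for s ∈ [0, t_tp], and decays as
d(s) = A · cos²(π s / (2 T_d)).  The decay span T_d is fixed analytically so
that d crosses 5 % of the amplitude exactly `relaxation_time` after the
peak: T_d = π t_r / (2 arccos √0.05) ≈ 1.1677 t_r.  This form is smooth at
the peak, has analytically invertible anchors (onset, peak, 5 % decay), and
reproduces the rounded rise/decay morphology of measured contraction
profiles.  Waveform validity enforces 1:1 capture — t_tp + t_r must be
shorter than the pacing period, and the full decay tail may not overlap the
next onset — otherwise an invalid-protocol error is raised.  Onsets repeat
at the pacing frequency starting 50 ms into the record; onset jitter is
zero by default (field-stimulated samples) and available as a Gaussian SD.

Treatment effects perturb the waveform before sampling: an amplitude scale
(the caffeine-like preset uses 1.3, a positive inotropic response), signed
shifts of time-to-peak and relaxation time, and a beat-duration shift that
lands on the relaxation limb (the KCl-like preset lengthens the beat by
10 % of the untreated duration).  These presets are sensitivity-test
fixtures, not pharmacological claims; both are freely configurable and may
be signed either way.

## Rendering

Three geometries are rendered: a grey **banded rod** (cosine band grid along
and across the long axis), a **fog rod** (spatially correlated speckle with
a diffuse, phase-contrast-like soft edge), and a round **cardioid**
(radially shaded disc with correlated speckle and a bright halo).  Rods
shorten longitudinally about their centroid by the factor 1 − d(t) with
constant width; cardioids shrink radially by the same factor.  All textures
are defined in object coordinates and deform with the geometry, so the
rendered boundary displacement equals d(t) times the half-extent exactly.

Rasterization evaluates the texture on a 4× supersampled grid restricted to
the geometry's bounding box and box-downsamples, preserving sub-pixel
motion at the small amplitudes that matter (a 0.3 px/frame tip excursion is
typical).  The background is a flat level plus a *static* fixed-pattern
speckle (SD 0.04 intensity), as a real field of view carries — a perfectly
featureless background would give optical flow nothing to anchor to and is
unrealistically hostile to it.  Per-pixel i.i.d. Gaussian noise (SD 0.01 by
default) is added per frame and intensities are clipped to [0, 1].  A fixed
spec + seed reproduces clips bit-identically.

Default study conditions, chosen once to mirror the acquisition settings
this package targets: single cells are 113 µm banded rods (25 µm wide,
12 px band period) in a 160×120 px frame at 1 µm/px, filmed 5 s at 143 fps
and paced at 0.5/1/2 Hz with amplitude 0.08, t_tp 120 ms, t_r 200 ms (the
waveform fits 1:1 capture at 2 Hz).  Cardioids are 454.13 µm discs in a
160×160 px frame at 4 µm/px, filmed 10 s at 143 fps and paced at
0.5/0.75/1 Hz (1 Hz is the highest rate with 1:1 capture) with amplitude
0.05, t_tp 250 ms, t_r 350 ms.  The in-silico time-variant experiment uses
a 150 ms baseline time-to-peak with the 200 % and 50 % conditions at
constant amplitude, rendered noise-free: those videos model clean
procedural renders, not camera acquisitions, so the camera-noise model does
not apply to them.

## The three trackers

**Intensity (frame difference).**  c(t) is the mean |frame_t − frame_ref|
over all pixels, in arbitrary units, against a fixed reference frame.  The
default reference is the minimum-activity frame (smallest total difference
to its temporal neighbours, ties to the earliest), which lands in diastole;
`first` uses frame 0.  An optional binarized mode thresholds the difference
image at a fraction of the clip-wide maximum and reports the moving-pixel
fraction; the threshold is exposed because no canonical value exists.
Profiles are kept in raw a.u. and min–max normalized only for display.

**Dense optical flow.**  The speed profile is the mean per-pixel flow
magnitude between successive frames × pixel size × fps (µm/s), averaged
over *all* pixels (a foreground mask is available but off by default, since
including the background dilutes magnitude but not timing).  The default
backend is iterative Lucas–Kanade dense flow (scikit-image, radius 5, two
warps); correctness is defined by the translation contract — mean vector
within 0.25 px/component of a pure translation — not by the backend, and an
in-repo exhaustive block-matching estimator (integer SSD search with
parabolic sub-pixel refinement) serves as the independent oracle and
fallback.  Flow samples are timestamped at inter-frame midpoints.
Featureless frames return a zero field with a low-confidence warning.

Beat segmentation needs a contraction-like trace, which a speed-only
tracker does not emit.  The package integrates one from the flow itself:
the inward radial flow component about the first frame's intensity
centroid, weighted by local gradient magnitude (flow is only informative
where there is texture), median-re-centred (diastole dominates a paced
record, so the median rate estimates the zero-motion bias) and cumulatively
summed.  The trace's amplitude is not calibrated to µm of boundary motion —
only its morphology is used, and it correlates > 0.9 with the true
deformation on the synthetic benchmark.  A slow residual drift remains,
which the beat-segmentation baselining absorbs (below).

**Marker tracking.**  A kernel (uniform patch by default; disc and cone map
to radially weighted patches) is captured on frame 0 — manually placed or
auto-placed at the top-k non-overlapping local-variance maxima — and
followed by normalized cross-correlation within a search window around its
previous position.  Candidate displacements are bounded at 5 px/frame; the
bound must stay below the texture period, or the tracker can lock onto the
neighbouring band of a periodic pattern.  The correlation peak is refined
to sub-pixel precision by a 3-point parabola per axis, skipped when the
match is exact (a parabola on an asymmetric surface around a perfect match
would add a spurious ~0.02 px offset).  Ties at equal correlation resolve
to the smallest displacement; correlation below 0.5 for more than 5
consecutive frames raises a lost-track error naming the frame.  The patch
is not refreshed by default (drift avoidance); periodic refresh is
available.  Displacement is the distance from the frame-0 position × pixel
size; speed is the rectified step length × pixel size × fps.

## Beat analysis

The speed profile is the rectified derivative of the contraction profile.
The default scheme is the forward difference timestamped at the left frame,
deliberately carrying the slight temporal anticipation a ratio-of-
increments derivative produces; a central-difference scheme is available.

Segmentation finds contraction-profile peaks (3-sample smoothed copy;
minimum separation of half a pacing period when a hint is given, prominence
otherwise) and anchors each beat: onset A is the first sample above
`onset_epsilon` (default 0.05) of the beat's peak — the noise-robust
operationalization of "first value different from zero" — and end E is the
first sample after the peak at or below 5 % of it.  Two numerical choices
matter here.  First, the diastolic baseline is estimated per beat as the
10th percentile of the profile between neighbouring peaks, with separate
pre- and post-peak estimates: a global minimum would sit at the intensity
tracker's isolated zero (its reference frame) below the diastolic noise
floor, and a global quantile strands the 5 % criterion when the
flow-integrated trace drifts.  Second, anchor C — the start of relaxation,
graphically defined between the two speed peaks — is fixed at the
contraction-profile peak, making t[θr] the interval from relaxation onset
to the relaxation-speed peak.  B and D are the rectified-speed maxima on
the ascending and descending limbs (phase split on the smoothed copy, raw
values for magnitudes).  Incomplete trailing beats are dropped; a monotone
beat raises a missing-anchor error.

`time_to_peak` refines the onset by linear interpolation of the epsilon
crossing and the peak by a 3-point parabola, giving sub-frame precision on
smooth profiles.  Note the measured onset is the epsilon crossing, not the
true d(t) lift-off: on the raised-cosine rise the crossing sits at a fixed
fraction (arccos(0.9)/π ≈ 14.4 %) of the true time-to-peak, so recovery
tests compare against that analytic value, and ratios between conditions —
the time-variant experiment's output — are unaffected because the offset is
proportional.

## Comparisons and classification

Treatment deltas are treated-minus-control differences of group means per
(tracker, frequency, parameter), emitted both raw (ms or profile units) and
normalized by the control mean, covering both readings of a
control-normalized report.  Frequency ratios divide each parameter's mean
at the higher pacing rates by the lowest-rate mean.  Cross-tracker
agreement reports pairwise mean absolute difference and Spearman rank
correlation per parameter over beats aligned on beat index.  Two-way ANOVA
(statsmodels OLS + anova_lm) and a Kolmogorov–Smirnov normality check are
exposed as conveniences over standard routines, not re-derived.

The classification benchmark assembles one labelled dataset per tracker ×
frequency × sample type — 18 for the full two-sample-type, three-frequency,
three-tracker grid — with the six beat parameters as features.  The
protocol is: rebalance first (subsample the overrepresented class without
replacement), then a stratified 0.80 train/test split, then fit and score.
Hyperparameters, unstated in the protocol this mirrors and therefore fixed
here as package defaults: random forest with 200 trees and default feature
subsampling; SVMs with C = 1, polynomial degree 3, features standardized on
training statistics.  All randomness derives from one master seed via a
seed sequence.

## What the generator does and does not emulate

It emulates: rod- and spheroid-shaped samples with deforming textures,
longitudinal/radial shortening with exact scalar ground truth, pacing
protocols with 1:1 capture, treatment-like waveform perturbations, camera
noise, and a static textured background.  It does not emulate:
photorealistic rendering, intracellular calcium or electrophysiology,
sarcomere-level striation dynamics, out-of-plane (3-D) motion, focus drift,
illumination flicker, or motion of neighbouring debris.  Passing the
recovery tests therefore demonstrates that the trackers and the beat
analysis are correct on controlled deforming imagery with realistic noise —
not that any tracker is robust to every artefact of real microscopy.  The
classifier benchmark's feature-level tables (used for the 18-dataset
structure and calibration checks) apply the real beat-analysis code to the
analytic deformation trace and emulate the three measurement channels with
independent seeded jitter (3.5 ms on times, 2 % on magnitudes); they test
the dataset assembly and classification machinery, not the trackers.

## Problem sizes

The default test and acceptance runs use the study conditions above: 715
frames per cell clip, 1430 per cardioid clip, one replicate per frequency
for the protocol beat-count checks, three seeded single-beat clips (186
frames each) for the time-variant recovery, and 20 seeds for classifier
calibration.  These sizes were chosen as the smallest grids that exercise
every condition of the protocols.

## Known limitations

The flow-integrated contraction trace is morphology-only (uncalibrated
amplitude, slow drift).  The intensity profile is a nonlinear function of
displacement — near-saturation once displacement exceeds the texture
period, convex near zero under noise — so its a.u. magnitudes are not
comparable across clips with different textures.  The marker tracker
assumes locally rigid motion and a per-frame displacement below its search
bound.  AVI support covers the uncompressed 8/24-bit DIB frames the package
itself writes, not arbitrary codecs.  Beat segmentation assumes a paced,
quasi-periodic record; arrhythmic or fused beats are dropped rather than
resolved.
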