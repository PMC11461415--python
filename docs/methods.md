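# Methods

This note documents the models, defaults and numerical choices behind
`gazeroi`, and what the synthetic tests do and do not establish about real
recordings.

## Screen geometry and units

All spatial quantities convert between pixels and degrees of visual angle
linearly per axis: a 1920×1080 frame subtending 47.5° × 27.8° at 62 cm gives
40.42 px/° horizontally and 38.85 px/° vertically. The linear (flat-screen)
approximation is accurate to well under a pixel over this field of view and
is applied symmetrically in both the analysis and the generator, so no bias
can enter through it. Coordinates are 0-based pixel centres, origin top-left,
y downward; timestamps are milliseconds from the start of the analysis
window (default 0–12 000 ms, the period during which the perpetrator is in
view; configurable because exact segment boundaries differ per stimulus).

## Dynamic ROIs and sample assignment

ROI masks are per-video-frame binary images (25 fps), run-length encoded in
both the file format and the in-memory container; a gaze sample at time *t*
uses the masks of frame ⌊t·fps/1000⌋, held constant within the frame — the
tracks are 40× sparser in time than 1000-Hz gaze, and no interpolation is
attempted.

Each mask is dilated by a safety margin, default **0.5° per axis**, to
absorb tracker inaccuracy. Because the pixel grid is anisotropic the
structuring element is an ellipse (≈20.2 × 19.4 px at default geometry).
Dilation is computed as a thresholded anisotropically weighted Euclidean
distance transform restricted to the mask's padded bounding box — exactly
equivalent to morphological dilation with the discrete elliptical kernel
(asserted in tests) but orders of magnitude faster on HD frames.

Overlaps are resolved ordinally, never by area weighting: the first match in
the priority order `critical_object, perpetrator_head, perpetrator_body,
victim_head, victim_body` wins; samples matching nothing (including
off-screen coordinates) are labelled `other`, so the label set partitions
retained samples and per-participant TVTs sum to exactly 100%. Samples with
saccade or missing events pass through flagged *excluded* and enter no
denominator.

Head ROIs, where not provided, are derived from whole-body masks: an
ellipse is fitted by image moments (centroid, second-moment orientation) to
the top fraction of the mask's vertical extent, with axes rescaled so the
ellipse area equals the selected region's pixel area. The top fraction
defaults to **0.15**, a value chosen once as anatomically plausible for a
standing figure; there is no principled external reference for it, so it is
exposed in the API. A 1/12-per-pixel variance correction keeps thin regions
from degenerating.

Size equalization across conditions rescales one label's masks
isotropically about their per-frame centroids by a single condition-constant
factor until the time-averaged pixel area matches the grand mean within 1%
(the factor is refined by a fixed-point iteration because nearest-neighbour
rasterization makes realized area deviate slightly from factor²).

## Data-quality metrics

*Accuracy* is the tracker-reported validation error; when both eyes are
recorded, the eye with the lower error is selected (ties default to the
left eye; configurable). *Precision* is RMS sample-to-sample angular
displacement, computed by default over consecutive fixation-labelled
samples only — the field's convention, and the choice is exposed because
either scope is defensible. *Data loss* divides missing samples by the
count nominally expected from the sampling rate and window duration, since
missing samples carry no timestamps of their own in some exports; rows
absent from the file are counted as missing.

## Time-course statistics

Bins of width Δt (default 100 ms) are anchored at the window start as
left-closed intervals [(k−1)Δt, kΔt); this differs from the half-open-left
convention (0, kΔt] only in which boundary sample joins which bin, and keeps
a sample at exactly t = 0 inside the partition. The final partial bin is
kept with its true denominator. Bins whose (cumulative) denominator is
empty propagate NaN. The cumulative curve's final value equals the relative
TVT by construction; this identity, the per-bin 100% partition, and
equality with a brute-force double-loop implementation are verified over
random streams.

Two TVT denominators exist: `retained` (default — the per-condition label
partitions of published dwell tables sum to exactly 100, which only a
retained-sample denominator produces) and `window` (nominal sample count of
the whole window) for the literal "percentage of segment duration" reading.

## Planned contrasts and Bayes factors

Contrasts use only the two groups involved: pooled variance, df = n_A+n_B−2.
One-tailed tests orient *t* so the predicted direction is positive and take
the upper tail; Cohen's *d* is the absolute standardized mean difference.
Degenerate input (zero pooled SD with equal means) returns t = 0 by
convention; with unequal means it is an error.

The JZS Bayes factor places a Cauchy(0, r) prior on the standardized effect
δ, with the default scale r = √2/2. The H1 marginal likelihood is the
integral of the noncentral-t density over the prior, evaluated by adaptive
quadrature split at δ = 0 and at the likelihood peak (relative tolerance
1e-9; non-convergence raises). One-sided alternatives use the prior
*truncated* to the predicted sign (density doubled), not a posterior-odds
correction — this is what makes an effect observed opposite to the
prediction yield large BF01 rather than a value near 1, and it satisfies
the mixture identity BF10_two = (BF10⁺ + BF10⁻)/2, which the tests verify.
An independent Monte-Carlo route (averaging the noncentral-t density over
10⁶ prior draws) agrees with the quadrature to well under 1%.

Evidence bands on B = max(BF01, 1/BF01): < 1.5 inconclusive, then weak,
moderate, strong, very strong, extreme at 3, 10, 30, 100, signed by whether
BF01 exceeds 1. The 1.5 lower edge is the band that renders all bundled
published symbols consistently (values of 1.25 and 1.36 classify as
inconclusive while 1.55 and 1.93 classify as weak); standard tabulations
draw this edge at 1 or 3, so the boundary is configurable.

Because the bundled group summaries are printed to 2 decimals, statistics
recomputed from them can differ from published full-precision values by the
propagated effect of input rounding. Tests therefore allow half a unit of
printed precision *plus* a bound obtained by perturbing all four inputs by
±0.005; this is error propagation, not a tuned tolerance.

## Memory scoring

The module starts at per-participant tallies of correct/incorrect details —
scoring free text against an answer key is human work. Accuracy is percent
correct; inter-rater agreement is the Pearson correlation of two raters'
counts (not proportions; counts are what raters actually produce, and the
choice is exposed) over ≥3 shared participants.

## Synthetic-data generator

The generator emulates the study's recording regime: 12-s windows at
1000 Hz, alternating lognormal fixations (μ = 5.5, σ = 0.35 on the ms
scale, ≈245 ms median — a conventional scene-viewing shape, not an
empirical claim) and 30-ms saccades; fixations land on the scheduled ROI's
centroid plus a per-fixation Gaussian placement error (default SD 0.1°) and
per-sample tremor (default SD 0.0096°, giving RMS-S2S ≈ 0.019°); missing
samples are injected i.i.d. at rate 0.017. Fixations on moving ROIs track
the centroid across frames, emulating smooth pursuit. "Other" dwell targets
the screen point maximally distant from every ROI across the track.

Dwell schedules are realized by a deterministic largest-deficit allocation
of fixations to labels, so each session's realized dwell share tracks its
configured share to within about one fixation duration (≲0.5 percentage
points over 12 s); a per-fixation multinomial mode provides the fully
stochastic alternative. The deterministic default was chosen so the
ground-truth manifest is tight: closed-loop tests then isolate assignment
and bookkeeping errors instead of burning their tolerance on scheduling
noise. Cohorts draw each participant's target-label share from a normal
distribution around the condition mean (default SD 0.08 — the order of the
published between-subject SDs) and memory tallies binomially (default 40
details at p = 0.77, the published accuracy regime).

All entry points are deterministic given their seed; sub-streams
(scheduling, noise, missingness, tallies) derive from the seed by fixed
offsets, and cohort session seeds by an affine map, so any component can be
regenerated independently.

**What the generator does not emulate:** saliency-driven scanpaths,
anticipatory saccades, pursuit gain < 1, blink dynamics (missingness is
i.i.d., not bursty), calibration drift, or any correlation between gaze
behaviour and memory performance. Closed-loop passes therefore validate the
pipeline's bookkeeping and statistics — not claims about real observers.

## Problem sizes used in tests

Synthetic validation runs at the study's geometry. The effect-recovery and
null-calibration checks use 200 replicate cohorts of n = 20 per condition
at 250 Hz over 12-s windows with a static scene (the package's choice of a
desk-scale design: the injected dwell-share effect of d = 0.5 against a
between-subject SD of 0.06 gives negligible attenuation from scheduling
noise, so the mean recovered d̂ should sit within ±0.1 of 0.5). Published
dwell-time means, time-course figures, memory means and inter-rater
correlations depend on the original raw recordings and rater data and are
not recomputable from summaries; they are covered only by these
closed-loop synthetic properties.

## Known limitations

* Frame-constant masks mean a sample during a fast ROI movement can be
  assigned against a mask up to 40 ms stale.
* Nearest-neighbour mask scaling limits size equalization on very small
  masks (boundary error ~perimeter/2 pixels).
* The head-ellipse fit assumes the head occupies the top of the body mask;
  seated or occluded figures may need a hand-tuned top fraction.
* RLE masks are decoded densely on access; extremely long moving tracks
  trade memory for the decode cache.
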