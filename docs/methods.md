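# Methods

This note documents the models, numerical choices and known limitations of
`saccmap`.  It is written for users who want to judge what the pipeline's
results do and do not establish.

## Geometry

All positions are screen-centered Cartesian degrees of visual angle (dva),
+x rightward, +y upward.  The fixation target (ft) and saccade target (st)
straddle the origin at (∓6, 0), 12 dva apart; the cue, when shown, sits at
(0, ±6).  The remapped location of a stimulus is its screen position minus
the saccade vector, so the remapped cue is at (−12, +6) in the canonical
(rightward-saccade, top-cue) frame and the fixation target is the remapped
location of the saccade target.  Leftward-saccade and bottom-cue trials are
collapsed onto the canonical frame by sign flips before any tabulation.

The tested positions are every second intersection of a 9-column × 7-row
lattice with 3-dva spacing (24 × 18 dva).  The parity class containing the
four positions of interest holds **31** nodes (rows at y ∈ {−6, 0, +6} hold
5 nodes, rows at y ∈ {−9, −3, +3, +9} hold 4).  Published descriptions of
this design mention 32 positions; the identity of a 32nd node is not
recoverable from the lattice geometry, so the grid is built from geometry
(membership of the positions of interest is what the analysis needs) and
the node count is logged.

Eccentricity groups bin each node's distance from ft into five ranges
(0; ~4.2–6; ~8.5–9.5; 12–~13.4; ~15.3–16.2 dva).  Five far border nodes
(17.5–19.0 dva) fall outside every printed range; `eccentricity_group`
raises for them in strict mode and assigns the nearest range (group 5) in
the non-strict mode the pipeline uses.  The "surround" of a position of
interest is its diagonal-neighbor set at 3√2 ≈ 4.24 dva; the remapped cue
sits on the grid border and has only two in-grid neighbors, which are used
with a logged warning.

The 12 flickering distractor streams form a 4-column × 3-row matrix
(columns ±3, ±9; rows 0, ±6 dva) shifted to one of 15 placements
(horizontal −3/0/+3, vertical −6…+6 dva).  A placement *overlaps the
targets* when a stream center coincides with ft or st, which happens for
the 6 placements with a horizontal shift of ±3 and a vertical shift in
{−6, 0, +6}.

## Synthetic generator

The generator is the package's ground truth; its defaults define the study
conditions the tests probe.

**Schedules.** Conditions (no cue / cue 50 ms before dt / cue 200 ms
before dt) are drawn with equal probability; saccade side and cue side are
50/50; the 15 matrix placements cycle in shuffled blocks; the fixation
period is uniform over 500–900 ms in 50-ms steps; the discrimination
target (dt) onset is uniform over 50–175 ms after saccade-target onset,
+25 ms on overlap placements (compensating the slower overlap saccades so
dt timing relative to the saccade stays homogeneous).  dt positions are
drawn over the grid with the protocol's 30% down-weighting of the 9 nodes
in the two rows most distant from the cue (cue trials) or of the 18 nodes
in the two top and two bottom rows (no-cue trials).  Tilt signs are
counterbalanced per node *and condition* — i.i.d. signs would leave ~18%
of node cells below the 5-per-sign tabulation cut at realistic trial
counts, which no real constant-stimuli design would accept.

**Gaze.** Fixation jitter is i.i.d. Gaussian per axis per 1-ms sample
(SD 0.05 dva, EyeLink-class noise).  Latency is Gaussian with mean 186 ms
(+31.56 ms on overlap placements, matching the reported overlap split of
217.56 vs 186.00 ms) and SD 20 ms.  The saccade follows a raised-cosine
velocity profile with main-sequence duration 21 ms + 2.2 ms/dva (47.4 ms
at 12 dva); the landing point scatters isotropically with SD 0.5 dva.
Blinks (probability 0.01 per trial) blank a 50-ms gap at a random time.
With these defaults the design-level Monte-Carlo oracle
(`expected_inclusion_rate`) predicts ~87% of trials passing the inclusion
rules.  The nominal design target was ~90%, but with dt onsets uniform
over the printed 50–175 ms interval and the reported latency means, the
dt-in-the-last-150-ms rule alone caps the attainable rate near 88% even at
implausibly tight latency SDs; 87% is the closest realistic operating
point.

**Observer.** Sensitivity is an equal-variance signal-detection model:
P(report cw | cw target) = (1−λ)·Φ(d′/2 − c) + λ/2, with response bias
c = 0 and lapse λ = 0 by default.  d′ at position p scales as
gain(p) · d′_ref · tilt/θ_true(p), where θ_true(p) = 4.42° + 0.615°/dva ·
eccentricity is the generator's true threshold profile (anchored at the
reported 4.42° foveal and 14.10° far-eccentricity thresholds) and
d′_ref = 2·Φ⁻¹(0.85) ≈ 2.073 makes a gain-1 observer sit exactly at the
85% criterion when the tilt is at threshold.  The gain field is a baseline
of 1 plus Gaussian attention loci (spatial SD 0.9 dva, well inside the
4.24-dva inter-node distance, so loci are spatially specific by
construction):

| condition | loci (amplitude) |
|---|---|
| no cue | st (1.0) |
| cue 50 ms before dt | st (1.0), cue (0.9) |
| cue 200 ms before dt | st (1.0), cue (0.9), remapped cue (0.8) |

Amplitudes preserve the empirically observed ordering (saccade target >
cue > remapped cue; no locus at the remapped cue when the cue comes too
late for remapping to develop) and were sized by a design-time power
analysis: with 8 participants × 1500 trials (~14 included trials per node,
condition and participant), a locus must produce a normalized-d′ gap of
roughly 0.3 over its surround for the paired bootstrap to resolve it with
>95% power, which at the d′ ceiling imposed by the 0.01/0.99 rate
correction requires amplitudes ≳0.8.  The threshold-*task* observers are:
flat gain (peripheral variant, thresholds measured during fixation at the
cued location), and a negative locus at ft (amplitude −0.7, SD 2 dva) for
the foveal variant, emulating saccade preparation drawing attention away
from fixation and reproducing the several-fold higher foveal threshold
measured during saccade tasks.

All randomness flows from one session seed through named substreams
(schedule, gaze, responses), so sessions are bit-reproducible.

## Saccade detection and inclusion

Positions are smoothed with a centered 20-sample moving average (invalid
samples propagate), and 2-D velocity comes from ±1-sample central
differences; edge samples are undefined.  The detection threshold is
median(speed) + 3·SD, where SD combines per-component robust variances
median(v_c²) − median(v_c)² (the median-based estimator; a plain sample SD
would be inflated by the saccade itself, and the same estimator applied to
the speed magnitude is degenerate because the median commutes with the
square).  The threshold is computed per trial from that trial's defined
samples.  Runs of supra-threshold speed lasting ≥ 20 ms are events.

Because the statistical threshold sits at ~2% of peak speed, its first
crossing on the heavily smoothed velocity *anticipates* the physical onset
by up to half the smoothing window.  The reported onset is therefore
refined to the first run sample at ≥10% of the run's peak speed — a
percentage-of-peak criterion that tracks the event's own rising flank.  On
clean synthetic 12-dva saccades this leaves an onset error of +0.9 ± 0.4 ms;
without refinement the error is −3.5 ± 0.6 ms, which would bias every
latency estimate.  The offset stays at the threshold re-crossing, so the
end position is read after the eye has essentially settled.

Inclusion flags: fixation excursion beyond 2.0 dva before the primary
saccade (FIX_BREAK), landing more than 2.0 dva from st (BAD_LANDING),
latency < 25 ms (EARLY) or offset > 350 ms after st onset (LATE), any
invalid sample up to 100 ms past the saccade offset (BLINK — the protocol
does not define the blink window; this one covers everything that can
affect the analysed epoch), dt offset outside [0, 150] ms before saccade
onset (DT_OUT_OF_WINDOW), a second ≥2-dva movement (MULTI_SACCADE), or no
qualifying saccade (NO_SACCADE).

## Psychometrics

The psychometric model anchors chance at 50% with no lapse parameter:
P(correct; θ) = 0.5 + 0.5·Φ((θ−μ)/σ) over tilt magnitude (fits are over
correct rate versus |tilt|, not signed tilt).  Fitting maximizes the
binomial log-likelihood over (μ, log σ) with a deterministic 9×7 start
grid followed by Nelder–Mead refinement of the best three starts, so
repeated fits are bit-identical without a seed.  Degenerate blocks are
flagged unstable with thresholds clamped to the tested interval:
all-correct → lowest tested tilt, chance-level (pooled accuracy ≤ 0.55 and
top-level accuracy ≤ 0.65) → highest tested tilt; fitted thresholds
below 0 or above twice the largest tested tilt are clamped likewise.  The
per-group thresholds (tilt at 85% correct) are linearly interpolated over
the group mean eccentricities, with constant extrapolation outside, to set
the tilt shown at every grid node.

## Sensitivity and maps

Hits and false alarms are clockwise reports to clockwise and
counterclockwise targets; rates of exactly 0 or 1 become 0.01/0.99 before
the z-transform (each rate corrected independently — the rates are the
only quantities entering z).  Below-chance d′ stays negative.  Node cells
with fewer than 5 trials of either tilt sign are not tabulated; they are
filled by natural-neighbor interpolation exactly like untested lattice
intersections, and the filled value stands in for that participant in the
position-of-interest comparisons so the participant pairing stays
complete.  Normalization is min–max per participant × condition over its
tabulated nodes.  Cue-condition timing is re-checked against the realized
saccade: late-cue trials must have the cue offset ≤ 175 ms before saccade
onset, early-cue trials > 175 ms; violations are dropped with a logged
count (with the generator's timing the classes are consistent by
construction).

Natural-neighbor (Sibson) interpolation is implemented by area stealing:
the query is inserted into the Voronoi diagram of the tested nodes and the
weight of node i is the fraction of the query's new cell carved out of
node i's old cell (polygon clipping by bisector half-planes).  It is exact
for linear fields inside the convex hull — the property the tests use as
an oracle.  Queries exactly on the hull boundary take the on-hull limit
(linear interpolation along the containing Delaunay edge); hull-exterior
intersections copy the nearest node (logged; ties broken by node index in
(y, x) order).  Display upsampling uses a separable Lanczos-3 kernel,
mirror-padded at half-sample boundaries and normalized per output sample,
which preserves constants and the matrix mean to machine precision.  The
default factor 8 is presentation only: **all statistics operate on node
values, never on interpolated pixels.**  Threshold maps evaluate the
threshold profile at each pixel's eccentricity from ft (concentric disks).

## Inference

Positions of interest are compared per participant against (a) the mean of
all other tested nodes and (b) the mean of their surround set, with a
paired bootstrap: participants are resampled with replacement, the
statistic is the mean difference, and the two-tailed p is twice the
smaller tail proportion of resampled differences (add-one smoothed),
floored at 1/B, with B = 10 000 by default.  Resamples draw n−1 of the n
participants: the plug-in variance of a resampled mean of n draws is
biased low by (n−1)/n, which makes the plain percentile test
anticonservative for small panels; the n−1 draw makes the resampled-mean
SD exactly s/√n.  Measured type-I error at nominal 0.05 is ≈0.07 for
n = 14 and ≈0.10 for n = 8 — still slightly anticonservative, as any
non-studentized bootstrap is at these panel sizes.  No multiple-testing
correction is applied across map nodes (a Bonferroni helper is provided,
off by default).

The repeated-measures ANOVA is the one-way within-subject decomposition
(SS_effect, SS_subject, SS_error = interaction), F = MS_effect/MS_error
with df (k−1, (k−1)(n−1)), partial η² = SS_effect/(SS_effect+SS_error), no
sphericity correction.  Latency ANOVAs use eccentricity groups 2–5 split
by stream overlap (the fixation-target group is sparse in overlap splits;
the four-group analysis matches the protocol's printed df pattern 3, 39);
landing-accuracy uses all five groups (df 4, 52 at n = 14).  Perfectly
additive matrices (zero error SS) are flagged degenerate.

## Problem sizes used in the shipped checks

The end-to-end locus-recovery check runs 20 replicate studies of
8 participants × 1500 trials with B = 10 000; criterion-recovery uses 100
sessions of 400 threshold trials; bootstrap calibration uses 10 000
replicate 14-participant Gaussian nulls at B = 2000; the detector check
uses 200 clean saccade trials and 200 pure-fixation traces.  These sizes
give each check a Monte-Carlo error comfortably below its acceptance
margin while keeping the whole suite in the minutes range.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
uniform 1-kHz sampling, a single stereotyped saccade per trial with
realistic latency scatter and landing error, stationary Gaussian fixation
noise, an attention field that is constant within a condition, and an
observer whose d′ is exactly linear in tilt.  Real data violate several of
these: drift and microsaccades during fixation, corrective saccades,
pupil-size artifacts around blinks, session-to-session threshold drift,
response lapses and biases, and attention fields that fluctuate trial to
trial.  Passing tests therefore establish that the *pipeline* is correct
and well calibrated — not that the effects would survive those additional
noise sources at a given sample size.  The detector's ±5-ms onset accuracy
is demonstrated for 12-dva saccades at 0.05-dva jitter; smaller saccades
or noisier trackers will degrade it.

## Known limitations

- Natural-neighbor filling is O(nodes × gaps) with polygon clipping per
  gap; fine for this 9×7 design, not meant for dense grids.
- The bootstrap retains mild small-n anticonservatism (see above); with
  8 participants, a nominal 0.05 test rejects a true null ~10% of the
  time.  Studentized resampling would fix this at the cost of departing
  from the difference-distribution convention.
- The 0.01/0.99 rate correction inflates d′ at low trial counts (ceiling
  cells), so maps built from few trials per node carry an upward,
  count-dependent bias that min–max normalization does not remove.
- Trial exclusion is offline only; no online gaze-contingent gating is
  modelled, and EyeLink EDF parsing is out of scope (plain-text adapters
  are the interface).
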