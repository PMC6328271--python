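# saccmap

Mapping visual attention around the time of a saccade.

When the eyes are about to move, visual sensitivity is not uniform: it
concentrates at the saccade target, at salient (cued) locations, and —
given enough time — at the *remapped* location of a cue, i.e. the retinal
position the cue will occupy once the eyes land (its screen position minus
the saccade vector).  `saccmap` turns raw 1-kHz gaze recordings and binary
orientation reports from a cued discrimination task into spatial maps of
that sensitivity, and tests whether the attention loci are spatially
specific.  A full synthetic generator (gaze traces plus a signal-detection
observer with a parametric attention field) makes every stage verifiable
without human data.

The package is aimed at visual psychophysicists and oculomotor researchers
who run gaze-contingent discrimination experiments and want a tested,
reproducible analysis path.

## The analysis in brief

1. **Saccade detection.** Eye positions are smoothed with a 20-sample
   moving average; 2-D velocity comes from central differences.  A saccade
   is a run of at least 20 ms during which speed exceeds
   `median(v) + 3·SD` with a robust (median-based, per-component) SD.
   Trials enter the analysis only if fixation stayed within 2.0 dva of the
   fixation target, the saccade started there and landed within 2.0 dva of
   the saccade target, latency was inside (25, 350) ms, no blink occurred,
   and the discrimination target (dt) extinguished in the 150 ms before
   saccade onset.
2. **Thresholds.** Performance versus tilt magnitude θ is fitted per
   eccentricity group with a guessing-floor cumulative Gaussian,
   `P(correct; θ) = 0.5 + 0.5·Φ((θ − μ)/σ)`, and the tilt at 85% correct,
   `θ₈₅ = μ + σ·Φ⁻¹(0.7)`, sets the tilt shown at each grid node in the
   main task (linear interpolation over eccentricity).
3. **Sensitivity maps.** Per participant, condition and grid node,
   `d′ = z(hit rate) − z(false-alarm rate)` (clockwise report to clockwise
   target = hit; rates of 0/1 corrected to 0.01/0.99), min–max normalized
   over the 31 tested nodes.  Untested lattice intersections are filled by
   Sibson natural-neighbor interpolation and the map is Lanczos-upsampled
   for display.
4. **Inference.** Paired bootstrap (participants resampled with
   replacement, 10 000 resamples, two-tailed p from the resampled mean
   differences) compares each position of interest against the average of
   all other nodes and against its four diagonal neighbors; saccade
   latency and accuracy effects of dt eccentricity use one-way
   repeated-measures ANOVA with partial eta squared.

## Worked example

Run the canned synthetic experiment (3 participants to keep it quick):

```python
from saccmap.pipeline import RunConfig, run_full

cfg = RunConfig(participants=3, trials_per_participant=1200, seed=7,
                bootstrap_B=2000)
res = run_full(cfg)

print(res["thresholds"].groupby("group")["threshold"].mean().round(2))
print(res["report"][res["report"].condition == "CUE_SOA200"]
      [["poi", "kind", "estimate", "p"]].to_string(index=False))
```

Output (seed 7):

```
group
1     3.76
2     7.68
3    10.28
4    12.34
5    16.97
Name: threshold, dtype: float64
  poi        kind  estimate        p
   ft     vs_rest -0.259000 0.001000
   ft vs_surround -0.118335 0.234883
   st     vs_rest  0.363638 0.001000
   st vs_surround  0.374184 0.001000
  cue     vs_rest  0.393461 0.001000
  cue vs_surround  0.375414 0.001000
remap     vs_rest  0.520957 0.001000
remap vs_surround  0.566540 0.001000
```

The five tilt thresholds grow from ~4° at fixation to ~17° at the far
eccentricities, reproducing the eccentricity-matched design.  In the
early-cue condition the saccade target, the cue and the cue's remapped
location all carry significantly higher normalized d′ than their
surrounding nodes (p < 0.05, paired bootstrap over participants) — three
distinct, spatially specific attention loci — while the fixation target
does not.  `res["maps"]` holds the group attention maps (7×9 node matrix
plus the upsampled field) and `res["subtraction_maps"]` the re-normalized
cue-minus-no-cue difference maps.

The same pipeline is available from the shell:

```bash
saccmap analyze --seed 7 --participants 3 --trials-per-participant 1200 --out results/run7
saccmap simulate --seed 7 --n-trials 100 --out results/session7   # raw gaze TSVs + trial log
```

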