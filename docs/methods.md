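# Methods

This note documents the models and procedural choices behind `perisacc`:
what the synthetic sessions emulate, how each analysis stage is defined,
which parameters matter, and what the package's tests do and do not
establish about real recordings.

## Session generator

### Trial design

A session consists of `n_trials` trials allocated to four conditions —
control, spatial-frequency change, shape change, combined change — at
exactly 1/2, 1/6, 1/6, 1/6 by stratified assignment: a fixed-composition
list (largest-remainder rounding) is shuffled once per session, so even
small sessions match the nominal mix exactly and condition counts are
reproducible. Pre-saccadic spatial frequency (1 vs 4 cpd) and target side
(left/right at `target_eccentricity`, default 8 deg) are balanced within
each condition. Timing per trial: fixation onset at t = 0; extrafoveal
stimulus onset after U(300, 700) ms; go signal after a further
U(500, 1000) ms (real-saccade mode) or, in simulated-saccade mode, the
scheduled translation onset after the same delay. All timestamps are
milliseconds on a per-trial clock, eye traces sampled at 1 kHz.

Default session size in the replicate analyses is 480 trials — within
the 322–1,440 trials per session the paradigm produces — with 40-neuron
populations; at much smaller change-trial counts the per-neuron
modulation-index distribution becomes noticeably skewed (it is a ratio
statistic), which inflates signed-rank rejections under the null.

### Eye kinematics

Saccades follow a straight-line minimum-jerk position profile
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ with a main-sequence duration rule
D = 2.7·A + 25 ms, giving peak speed 1.875·A/D — about 320 deg/s for the
task's ~7.5-deg saccades, matching the ~340 deg/s scale of the simulated
saccade profile, and comfortably above 100 deg/s throughout the interval
in which a frame-locked update can complete. Primary saccades undershoot
the target by 8% with 0.3-deg landing jitter per component (saccadic
undershoot is what makes corrective saccades common); post-saccadic
drift creeps toward the target at 1 deg/s; with probability 0.7 a
catch-up saccade corrects the residual error at a latency of
180 ± 25 ms after the primary saccade's end, delayed a further 15 ms on
intra-saccadic change trials. Fixational jitter is Gaussian-smoothed
noise with stationary SD 0.02 deg. Saccade latency from the go signal is
180 ± 30 ms (truncated at 100 ms).

The online update emulation mirrors the gaze-contingent protocol: the
first sample at which radial eye position exceeds the virtual fixation
window (default radius 0.75 deg) triggers a stimulus update that
completes at the end of the first display frame whose start is at or
after the trigger. The frame clock has phase 0 at trial start and period
1000/85 ms; a trigger landing exactly on a frame boundary belongs to the
frame starting there. Control trials record the same timestamp as a
fictive update. In simulated-saccade mode the image change occurs in the
first translation frame, so the fictive update is the end of that frame.
The window radius and duration rule together guarantee — by
construction, for the task's saccade amplitudes — that updates complete
intra-saccadically with at most a two-frame (23.5 ms) delay, while eye
speed is still above 100 deg/s.

### Spike model

Each neuron is an inhomogeneous Poisson process:

```
rate(t) = [baseline + release(t) + onset(t)]
            × (1 − pause_depth·1[saccade onset ≤ t ≤ saccade end + 10 ms])
            × (1 − onset-suppression(t))
          + gain(condition, mode) · burst(t − update)
```

- baseline: constant (default 20 spikes/s);
- release(t): Gaussian bump (amp 10 spikes/s, σ 30 ms) 80 ms after the
  fixation spot is removed — absent in simulated-saccade mode;
- onset(t): the extrafoveal stimulus-onset response. Properly foveal
  neurons have none or a *suppression* (default −5 spikes/s over
  40–160 ms post-onset, implemented by thinning); a positive amplitude
  injects a visual burst 90 ms post-onset and marks a neuron the
  screening stage must exclude;
- pause: multiplicative suppression of the background components from
  saccade onset to saccade end + 10 ms (default depth 1.0, a complete
  intra-saccadic pause). No pause without an actual saccade;
- burst: Gaussian bump in rate after the update, with foveated-SF-
  dependent parameters: latency 60 ms / amplitude 100 spikes/s for
  low-SF targets, 90 ms / 80 spikes/s for high (high-SF responses are
  delayed and weaker), σ 15 ms.

The prediction-error gain multiplies the burst amplitude: 1 on control
trials; `gain_sf_change` (default 1.5) on spatial-frequency changes;
`gain_shape_change_low_sf` / `gain_shape_change_high_sf` (1.15 / 1.4 —
shape changes are harder to detect when a salient low-SF texture
dominates the preview) on shape changes; and for combined changes a
configurable composition rule, by default subadditive on the excess
gains, 1 + α·((g_sf − 1) + (g_shape − 1)) with α = 0.8. **The gain is
applied only in real-saccade mode**: simulated-saccade trials receive
identical sensory drive (the same bursts) with gain 1, encoding as
ground truth the dissociation the analyses are meant to detect. Whether
that dissociation holds in any real dataset is an empirical question the
generator cannot answer; here it defines the recovery target.

Sampling is by exact superposition: the additive components are sampled
directly (homogeneous Poisson for the baseline; Poisson-count Gaussian
bumps truncated to the trial), and the multiplicative suppressions are
applied by independent thinning. This is distributionally exact for the
composed rate and orders of magnitude faster than grid-based thinning,
which is what makes the 100-replicate population analyses affordable.
`rate_on_grid` exposes the corresponding rate function for diagnostics;
expected spike counts equal its time integral.

A `burst_dominated_neuron` preset (baseline 5 spikes/s, no release
transient, complete pause, burst amplitude 150 spikes/s) serves the
parameter-recovery analyses: when the measurement-window peak is
essentially the burst, the population median modulation index approaches
the closed form (g − 1)/(g + 1), which recovery tests check to ±0.05.
With the default (baseline-contaminated) neuron the index is biased
toward zero, as it would be in any real neuron with nonzero background
rate.

### Randomness and reproducibility

All randomness derives from one root seed through counter-based
`SeedSequence` child streams keyed by purpose (trial allocation; trial
kinematics; neuron × trial spiking), so adding neurons never perturbs
trial-level randomness and any (config, seed) pair regenerates a
bit-identical bundle. Bundles serialize to a directory of RFC-4180 CSVs
plus `config.json` (schema-versioned); floats are written at 17
significant digits and parsed in round-trip mode, so write → read is
bit-lossless.

## Saccade detection

Radial speed is computed from positions smoothed with a ±5 ms moving
average, differentiated with a 5-point central difference (edges
replicated and excluded from detection), and combined as
√(vx² + vy²). Saccades are maximal runs of speed ≥ 20 deg/s, merged
across gaps < 20 ms, kept if ≥ 8 ms long — standard velocity-threshold
practice for 1 kHz coil-type traces; all four criteria are configurable,
since detection conventions differ between laboratories. Landing
position is the mean gaze over the 10 ms after the saccade end (robust
to drift). Microsaccades and saccades come from the same detector, split
at 1 deg amplitude for reporting.

Two detector properties worth knowing: raising the speed threshold never
increases the event count for movements separated by more than the merge
interval, but two movements inside one merged run *can* split into two
events at a higher threshold — the merge rule makes strict monotonicity
impossible in that corner. And detected onsets/ends sit a few
milliseconds inside the true movement (threshold crossing), so
catch-up-saccade latencies measured detector-to-detector carry a few
milliseconds of systematic offset.

Trial acceptance: landing strictly within 2 deg of the target center;
the update must complete between saccade onset and end
(`validate_update_timing` also interpolates eye speed at the update
completion, which should exceed 100 deg/s if the update truly fell
inside the movement).

## Response quantification

Spikes are aligned per condition to the real-or-fictive update (span
−300 to +300 ms; alignment to saccade end is available and leaves the
population effect signs unchanged on generated data). Rates are
estimated per trial with a Gaussian kernel (σ = 10 ms, 1 ms grid); the
kernel integrates to one spike of mass. Response strength is the peak
rate in 0–120 ms (low-SF foveated target) or 0–150 ms (high-SF) from
the update. Two peak semantics exist: the default takes the peak per
trial and averages across trials (the per-trial peaks also feed the
trial-level permutation test); `peak_of_mean=True` instead takes the
peak of the trial-averaged curve, which is less affected by the
positive noise bias of per-trial maxima. Peaks are strictly
window-local — only spikes inside the window enter the estimate — so
measures are bit-identical under any perturbation of spikes outside
their window.

Screening excludes a neuron if (a) its mean rate 50–150 ms after
extrafoveal stimulus onset exceeds the pre-onset rate (−100–0 ms) by
any amount — a deliberately maximal reading of "elevation, however
small"; onset *suppression* does not exclude — or (b) its mean
control-trial rate 0–100 ms after the fictive update is below
5 spikes/s. The 100-ms pre-onset baseline window is a package choice.

Population curves: each neuron's condition curve is divided by the peak
of its own control mean curve (low-SF conditions against the low-SF
control, high against high), then averaged with SEM; control peaks below
10⁻⁶ spikes/s skip the neuron with a warning.

## Statistics

- Modulation index (R_change − R_control)/(R_change + R_control), with
  the (0, 0) case defined as 0 under a warning.
- Permutation test on the difference of group means, two-sided: exact
  enumeration (observed labeling included, no correction) when the
  number of equal-size relabelings is ≤ 20,000, else Monte-Carlo with
  p = (c + 1)/(n_perm + 1), never zero. Default 10,000 repetitions;
  individual-neuron significance at p < 0.05.
- ROC AUC as the Mann-Whitney statistic with midrank ties, oriented so
  values > 0.5 mean higher measures on change trials. The timecourse
  uses per-trial spike counts in 50-ms bins stepped by 10 ms; 95%
  confidence bands come from a percentile bootstrap (default 2,000
  resamples) implemented as multinomial resampling of the per-bin count
  histograms, which is exactly the trial bootstrap but vectorized. How
  such bands "should" be computed is a genuinely open choice; the
  pipeline-level population curves instead average per-neuron AUC
  timecourses with ±1.96 SEM bands across neurons.
- Additivity: per neuron, the sum of the two single-feature indices
  against the combined-change index, Pearson r with two-sided p
  (Spearman available).
- Proportion comparisons ("fraction of neurons elevated") use a
  conditional exact two-proportion (Fisher) test — one defensible
  reading of a "binomial distribution fit".
- Rank-based tests (signed-rank, rank-sum, Kruskal-Wallis) and
  correlations are deliberately thin wrappers over scipy; all-zero
  paired differences return p = 1 with a warning.
- No multiple-testing correction is applied; every contrast is reported
  with its own p.

## Pipeline

`run_pipeline` executes generate → detect → screen → quantify → stats →
report. Every output CSV/JSON is registered in `manifest.json` with a
16-hex-digit hash of the full run configuration and of the file
contents; stages refuse upstream files stamped under a different
configuration. (The stamp lives in a sidecar manifest rather than inside
the CSVs, which stay plain RFC-4180.) Excluded trials and neurons are
logged with their rule. Identical configurations reproduce identical
bytes. The report table covers the eight standard contrasts — both
foveated spatial frequencies × {sf, shape, combined} changes with real
saccades, plus the two simulated-saccade SF contrasts — marking absent
ones rather than failing.

## What passing tests do and do not show

The generator reproduces the paradigm's *structure*: condition mix,
frame-locked intra-saccadic updates, main-sequence kinematics with
>100 deg/s updates, pause-then-burst firing with SF-dependent latencies,
and a saccade-contingent gain. It does not attempt fidelity to any real
neuron's rates, variability (Poisson only — no refractoriness, bursting,
or slow drift), correlations between neurons (all conditionally
independent), or real oculomotor idiosyncrasies (no blinks, torsion, or
tracker artifacts; noise is stationary). Parameter-recovery results
therefore validate the *analysis code* under a known generative model,
not claims about biological recordings. Baseline rates, burst
amplitudes, and trial-to-trial variability are not reported for the real
data this paradigm comes from; the defaults here are chosen to be
realistic in scale and to give the tests sensitivity, nothing more.

## Numerical notes

- Frame arithmetic uses a 10⁻⁹-frame tolerance so boundary triggers are
  assigned to the frame starting at the boundary regardless of float
  error.
- Permutation statistics compare with a 10⁻¹² slack so ties with the
  observed statistic count as extreme (conservative).
- Rate curves and peaks are evaluated on fixed 1-ms grids; the reported
  peak is the grid maximum, adequate for σ = 10 ms smoothing.
- Bundle round trips are validated bit-for-bit in the test suite.
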