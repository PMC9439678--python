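# Methods

This note documents the models, estimators, numerical choices and
known limitations of `neuropose`, and what the synthetic-data tests do
and do not establish about real recordings.

## Task and stimulus model

The tilt-discrimination task presents planar surfaces at all
combinations of 8 tilts (0–315°, 45° steps) and 4 non-zero slants
(15–60°, 15° steps) plus a frontoparallel plane (slant 0°, tilt
undefined), each at 4 distances (37, 57, 97, 137 cm): 33 orientation
conditions per distance, 132 unique poses.  One block contains one
completed trial per pose plus 8 frontoparallel trials per distance
(160 tilt-task trials) and 8 saccade directions × 4 repeats (32
saccade-task trials).  Stimuli last 1 s after a 300 ms fixation;
fixation is always at 57 cm.  Frontoparallel trials are
task-ambiguous; the generator draws their choices from a configurable
distribution (uniform by default, independent of any neuron's
preference — sessions' choice distributions and neuronal preferences
are uncorrelated by construction).

## Synthetic neurons

A ground-truth neuron has a Bingham orientation-tuning surface

    rate(n) = baseline + gain_D · exp(λ₁ (n·u₁)² + λ₂ (n·u₂)²)

with per-distance preferred orientation and gain.  Spike counts are
Poisson; spike times come from an inhomogeneous Poisson process at
1 ms resolution whose profile is: baseline during fixation, a step to
the condition rate at the visual latency (46 ms by default), an
optional choice component on frontoparallel trials (step or ramp from
the choice onset, von Mises-shaped across choices, κ = 4.7 by
default), and an optional pre-saccadic ramp on saccade trials
(von Mises across directions, κ = 6.3).  Counts stored in the trial
table are the number of spikes inside the response window
[visual latency, stimulus end], so counts and times agree by
construction.

*Within-trial dynamics are under-determined*: only mean rates are
constrained by tuning analyses, so the transient shapes (step vs ramp)
are free choices exposed in configuration.  Tests that depend on them
(onset recovery, growth rates) therefore validate the estimators given
the assumed shapes, not the shapes themselves.

**Shared gain and noise correlations.** Neurons simulated on one
"tetrode" share a per-trial multiplicative lognormal gain with mean
one.  Under this model two neurons with per-condition mean counts
m₁, m₂ and gain variance v have per-condition count correlation
m₁m₂v / √((m₁+m₁²v)(m₂+m₂²v)); `shared_gain_sd_for_noise_r` inverts
the condition-averaged prediction to hit a target mean noise
correlation (0.17 in the standard configuration), and the recovery
test confirms the estimator within ±0.03.  This is the minimal model
producing the noise/signal-correlation structure the pair analyses
consume; it does not emulate slow drifts, spike-sorting artifacts or
distance-dependent gain covariability.

**Cross-distance jitter.** The knob that controls true distance
tolerance scatters per-distance preferred orientations along one
random great-circle direction per neuron, each distance by an
excursion uniform in [0, jitter] degrees.  A one-sided single-geodesic
walk is used deliberately: the Bingham surface is antipodally
symmetric, so rotating preferences by ~90° in independent random
directions makes pairs of tuning curves *similar* again and the
tolerance–jitter relation non-monotone; along one geodesic the
pairwise scatter never exceeds the knob, and mean estimated tolerance
decreases monotonically over the 0–90° sweep (rank correlation −0.99
in the recovery test).

**Saccade trials.** Latencies are shifted-gamma (shift 100 ms, shape
2, scale 30 ms by default): positive and right-skewed.  Pre-saccadic
activity starts at −onset_frac · latency relative to the saccade
(onset_frac 0.8 by default) and ramps linearly to its peak at a
coalescence time (−59 ms), so longer-latency trials start earlier and
grow more slowly — the inverse growth-rate/latency rule.  Eye-velocity
traces are zero until the latency and cross the 150 °/s threshold
exactly there.

## Estimators and numerical choices

**Bingham fits** use bounded trust-region least squares (tolerance
1e−8, ≤500 evaluations per start), multi-started from the stimulus
orientations in descending order of observed rate; ties break to the
lowest start index.  The internal convention is λ₁ ≤ −|λ₂| ≤ 0 with
the preferred direction's exponent fixed at zero; the reported
"bandwidth" is |λ₂| (larger = narrower) and "isotropy" is the signed
λ₁ (more negative = more elongated), and Φ is reported modulo 180°
(an axis).  Swapping the concentration axes is compensated by rotating
Φ by 90°.  Fits with gain below 1% of the offset are flagged flat;
fits with λ₁ ≈ λ₂ flag Φ as unidentifiable.

**Separable fits**: alternating least squares with an SVD inner step,
iterated to ΔSSE < 1e−10 or 1000 iterations; identifiability fixed by
‖H‖₂ = 1, max F = 1, gain > 0.  ALS converges linearly, so factors are
accurate to ~√SSE-level rather than machine precision.  The additive
variant has the closed-form two-way-means solution.  The tolerance
index excludes zero-variance observed or fitted columns (correlation
undefined) and is NaN if all are excluded; it is reported unclipped
and can be negative for anti-correlated columns.

**Behavioral κ** is fit to the binned probability vector with the
discretised von Mises (density at the 8 bin centres renormalised over
bins) because choices are discrete (8AFC); κ is constrained to
[0, 18], and a boundary refinement returns the bound exactly when it
fits at least as well as the interior optimum.  Note that fitting the
discretised model to choices generated by snapping a continuous
von Mises error recovers a slightly smaller κ than the continuous
generator value (binning flattens the distribution); the estimator is
consistent for the discretised family, and monotone in the generator's
κ, which is what the behavior analyses require.

**Onset detection** always uses the same rule: per-1 ms-bin one-way
ANOVA on trial-level (or neuron-level) SDF values, first bin of a run
of ≥30 consecutive bins with p < 0.05.  SDFs use the causal kernel
k(t) ∝ (1 − e^(−t/τg))·e^(−t/τd), unit area, τg = 1 ms and τd = 20 ms
by default (configurable).  Two practical consequences: (i) SDFs need
~5τd of history to settle, so baselines are taken from settled regions
(the visual-latency routine starts its SDF inside the fixation epoch;
the quartile analysis defaults its baseline window to [−450, −300) ms,
clear of the grid's warm-up); (ii) the kernel smears brief transients,
so a 20 ms transient can produce a >30 ms significant run under the
default kernel at high trial counts — the sustain rule excludes brief
events only at a temporal resolution commensurate with the kernel.

**Iterative population choice onset**: the initial window is
[median visual latency, stimulus end]; responses are baseline-
subtracted and z-scored per distance, neurons screened by choice ANOVA
(p < 0.05), per-choice SDFs relabelled relative to each neuron's
preferred choice (argmax of window mean; ties to the lowest angle) and
averaged; the divergence onset redefines the window and the procedure
repeats (≤20 iterations; a previously seen onset terminates an
oscillation).

**Quartile analysis** partitions preferred-direction trials into four
near-equal groups by latency rank (stable sort), which also handles
degenerate all-equal latencies (flagged).  Coalescence is the time
minimising the summed squared deviation of the four mean curves from
their mean, searched from the latest quartile start to the alignment
event, earliest minimiser on ties.  Growth rates are least-squares
slopes from each quartile's start to coalescence, in units/s.

**Circular statistics** are implemented directly (no directional-
statistics dependency is assumed): Rayleigh p uses the standard
finite-sample approximation; the circular-median test is a two-sided
binomial sign test on the two open semicircles about the hypothesised
median (boundary angles excluded); the concentration-difference test
uses the Fisher-style variance ratio of 1 − cos deviations from each
sample's mean direction, referred to F(n₁−1, n₂−1), when both mean
resultant lengths are ≥0.7 (its applicability condition), and
otherwise a 2000-permutation test on the circular-variance difference
(also used when a sample is perfectly concentrated).  Angle
differences are wrapped to (−180°, 180°].

**Moderation regression** is ordinary least squares of the absolute
wrapped principal-tilt − saccade-preference difference on tolerance,
the choice flag and their interaction (fixed effects only; no animal
random effects).

**Type II regression** is the standardised major axis
(slope = sign(r)·SDy/SDx), chosen among type II variants for being
symmetric and closed-form.

## Problem sizes in the verification suite

Simulation sizes were chosen to make the checks informative at desk
scale: chance-rate at 100,000 trials; tolerance–jitter sweep with 200
neurons over ten jitter levels (5 blocks each, counts only); choice
onset recovery with 40 neurons (30% modulated, depth 20 spikes/s, 8
blocks) — the detected onset must fall within ±10 ms of the injected
190 ms and the late-window separation must exceed 5× its fluctuation
scale; noise-correlation recovery with 4 neurons × 40 blocks;
moderation-slope recovery with 50 simulations at n = 400 (generator
slopes 0.16 and −2.2).  Type-I calibration uses 1000 simulations for
the closed-form circular tests, 500 for the moderation interaction,
and 200–400 for the simulation-heavy families (per-bin-ANOVA onset
detection, Holm-corrected orientation screening); all are asserted
against the same ≤7% bound at α = 0.05.

## What passing tests do and do not show

The generator produces Poisson variability with a single shared-gain
factor, stationary baselines, exact 1 ms alignment and the configured
transient shapes.  Passing recovery tests shows the estimators are
correct and calibrated *under these conditions*; real recordings add
non-Poisson dispersion, latency drift, adaptation, eye-movement
confounds and sorting errors that the generator deliberately omits.
Analyses whose outcomes on real data depend on those factors (e.g.,
absolute onset values, tolerance distributions) should be read as
validated procedures, not as predictions of real-data values.

## Known limitations

- The separable model is rank-1 + offset only; higher-rank structure
  is out of scope.
- The Bingham normalisation constant is never needed (the unnormalised
  tuning-surface form is fit), so the fits are not probability models.
- `fit_vonmises_tuning` constrains gain ≥ 0; purely suppressive
  direction tuning is not modelled.
- The concentration-difference F test is approximate for moderately
  concentrated samples; the permutation fallback is exact-in-
  distribution but slower.
- Counts-only simulation skips spike times; analyses needing SDFs
  (latency, onsets, quartiles) require time-resolved simulation.
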