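# Methods

## Stimulus model

Dots are points in the fronto-parallel plane, coordinates in degrees of
visual field with the origin at fixation.  Initial placement is uniform over
the disc of radius 50° by area (radius ∝ √u), matching "randomly spaced"
without central clustering.  The coherent stimulus rotates the whole field
rigidly at ω = 30 deg/s (signed; positive = counter-clockwise).  The
incoherent stimulus adds, per dot and per axis, an independent sinusoid
A·sin(2πft + φ) with A ~ U(0.5°, 3°), f ~ U(0.2, 1.0 Hz), φ ~ U(0, 2π).
These perturbation ranges are generator choices, not measured values: small
relative to the field radius (so no wraparound is modeled), visually
plausible as local jitter, and zero-mean over their own period so the global
mean angular velocity is preserved.  Trajectories are sampled at 60
frames/s and exported as arrays; rendering, dome geometry and luminance are
out of scope.

`mean_global_angular_speed` reports the across-dot mean of each dot's net
unwrapped angular displacement divided by the window length.  For rigid
rotation this equals ω exactly.  For incoherent fields the sinusoid
contributes only its truncation residual at the window edges, so at 1000
dots over 20 s the mean sits well inside ±1 deg/s of ω; dots whose radius
falls below a numerical floor (origin crossing — angle undefined) are
excluded with a logged count.

## Synthetic EEG model

Epochs span −200…+400 ms at 1000 Hz (600 samples), 64 EEG channels (10-10
montage, coordinates from the standard template montage) plus two EOG
bipolars.  The signal is a sum of two spatiotemporal components:

| component | latency | temporal σ | peak amplitude | spatial spread |
|-----------|---------|-----------|----------------|----------------|
| early     | 190 ms  | 20 ms     | −8 µV at Cz    | 0.93 rad       |
| late      | 280 ms  | 15 ms     | +6 µV at Cz    | 0.80 rad       |

Temporal profiles are Gaussian pulses; spatial profiles are generalized
Gaussians exp(−(d/spread)⁴) over the azimuthal-equidistant projection of the
montage.  The exponent-4 kernel (a plateau with a sharp shoulder; exponent 2
recovers a plain Gaussian and is available as a parameter) makes the
"planted electrode set" — electrodes at ≥ half-maximal weight — compact and
insensitive to threshold choice, which is what the recovery tests need.
With the spreads above the early half-max set covers 16 central electrodes
from Fz to Pz and the late set 9 centro-parietal electrodes, mirroring the
qualitative topographies the analysis is meant to detect.  The opposite
signs of the two components encode the polarity reversal between the early
and late windows.

Condition structure: coherent-condition component amplitudes are multiplied
by an attenuation factor a = 0.7 (< 1: the vection-consistent stimulus
evokes smaller central responses).  For the early component only,
left-handers' condition difference (1 − a) is `group_effect_ratio` = 2 times
the right-handers' (a_left = 0.4), so the handedness contrast has a planted
effect in the early window and none in the late window.  Per subject, a
log-normal gain (σ = 0.2) scales the whole template and a Normal(0, 0.08)
jitter shifts both attenuation factors, creating between-subject
variability.  The ratio of 2 was set so that the planted group effect is
reliably detectable at the study's sample size (28 + 29 subjects): at the
template center the group contrast then sits near t ≈ 4.5, comfortably
above the p < 0.01 electrode threshold, whereas a marginal planted effect
would make "the test must find it" an assertion about luck rather than
about the test.

Noise per channel is pink (power ∝ 1/f, spectrally shaped white noise) at
8 µV RMS — half of it a single process shared across channels, modeling
spatial correlation — plus 3 µV white sensor noise.  At these levels the
sliding-window rejection criteria fire on well under 5% of artifact-free
epochs, so rejection calibration is testable.  The generator does not model
dipolar forward physics, CW/CCW differences (collapsed in all analyses),
latency jitter across trials, or non-stationary drift; passing tests
therefore demonstrate correctness of the *analysis* under a plausible noise
model, not robustness to every property of real EEG.

Artifacts: blinks are Gaussian pulses (σ = 35 ms, peak 150 µV) on vEOG with
0.8 gain on Fp1/Fp2 — the best-aligned 200 ms window then has SD ≈ 50 µV,
safely above the 35 µV criterion; range artifacts are one 100 ms sine cycle
of ±75 µV (150 µV peak-to-peak) in one random EEG channel.  Injection
returns ground-truth labels so the rejection rules can be tested for exact
agreement.

Behavior: per trial, vection presence is Bernoulli (0.95 coherent, 0.08
incoherent); present trials draw a log-normal onset latency (median 6 s /
12 s, truncated below the 20 s motion duration) and log-normal total
duration (median 13 s / 4 s, intervals closing by trial end); absent trials
rate strength 0.  The subject's strength level is tied to their EEG through
a Gaussian copula: `strength_brain_coupling` (default −0.4) is the target
rank correlation between the subject's expected signed coherent-condition
central amplitude and their strength reports.  The coupled quantity is the
signed amplitude — the same scalar the correlation analysis later extracts —
so a planted negative coupling is recovered as a negative ρ.  The default
sign matches the direction reported for real data (stronger vection with
lower central amplitude).

## Preprocessing choices

Filters are linear-phase FIR kernels (Hamming window, length ≈ 3.3/transition
width) applied in a single symmetric pass, which is exactly zero-phase;
reflection padding handles the edges.  Defaults: notches at 50/100 Hz
(±2 Hz), band-pass 0.1–30 Hz with transition widths 0.1/7.5 Hz.  The 0.1 Hz
transition gives a ~33 s kernel at 1000 Hz — appropriate for continuous
recordings; short fixtures should widen it via `FilterSpec`.  A fixed FIR
notch stands in for regression-based line-noise removal; the cutoffs are
what matter downstream.

The windowed SD uses the unbiased (n−1) denominator, and both rejection
rules are strict inequalities, pinned so boundary behavior is exact: a
window SD of exactly 35 µV keeps the epoch.  The range rule applies to all
EEG channels and not the EOG (a range rule targets EEG excursions; scope is
configurable).  Only full 200 ms windows are evaluated (9 per 600 ms
epoch).  The participant-exclusion rule is applied per condition on
artifact-free epoch counts (< 30 excludes); an "in two or more electrodes"
qualification sometimes attached to such rules is not implementable when
rejection is per-epoch, and is deliberately not modeled.

Window means use inclusive bounds (61 samples for 160–220 ms at 1000 Hz).
Grand averages weight subjects equally rather than pooling epochs, matching
the subject-level statistics downstream.

## Cluster permutation test

Electrode-level statistics are t-tests: one-sample on per-subject condition
differences (paired) and pooled-variance two-sample on per-subject
condition differences between groups (independent).  Zero-variance
electrodes get t = 0, p = 1 with a warning.  The electrode threshold is
two-sided p < 0.01; clusters are maximal adjacency-connected sets of
suprathreshold electrodes sharing the t sign; mass is the sum of member t
values.  Clustering is spatial only, since the tested quantity is one
scalar per electrode.

Adjacency defaults to Delaunay triangulation of the 2D-projected montage
with edges above 1.5× the median edge length pruned (median neighbor count
5 on the shipped 64-channel layout, graph connected); a fixed-radius method
is the fallback for degenerate layouts.

The null permutes per-subject sign flips (paired) or group labels
(independent), recomputing the electrode statistics and the maximum |mass|
each time (0 when no electrode passes the threshold); both reductions are
exact matrix identities, so the whole null is vectorized.  The observed
largest |mass| is significant when it exceeds the 99th percentile of the
null.  The Monte-Carlo p value uses the (1 + #{null ≥ obs}) / (n_perm + 1)
correction and does not count the observed data as a permutation; when the
permutation space holds fewer than 100 distinct relabelings the full space
is enumerated instead and p is the exact proportion.  Largest-cluster ties
break by member count, then lexicographically smallest member set, for
deterministic regression tests.  All clusters are reported; the decision is
based on the largest, and secondary clusters are not separately tested.

## Behavioral statistics

Rank-sum comparisons use average ranks, tie-corrected variance, and a 0.5
continuity correction; r = Z/√N with N the observations entering the test.
The Bonferroni family defaults to m = 8 (4 measures × 2 conditions) for
behavior and m = 4 per window for correlations — family sizes are
configurable because the convention varies.  Duration is the per-trial
*total* vection time (a trial can hold several vection intervals), and
strength medians include vection-absent trials at rating 0; per-participant
medians (not pooled trials) are the unit of analysis, so each participant
is one observation.  Latency and duration are undefined for participants
with no vection-present trials and are excluded pairwise.

Spearman's ρ uses average ranks and the t-approximation for p (adequate at
n ≈ 57); an exact permutation p is available for n ≤ 10 as a test oracle.
The correlated EEG quantity is the unweighted mean coherent-condition
window amplitude over the electrodes of the largest significant condition
cluster (the larger-|mass| of the two group-level contrasts), groups
pooled.

## Pipeline

`run_all` streams subjects one at a time (simulate → inject artifacts →
baseline → reject → window means), so memory stays flat in cohort size;
behavioral analyses include all subjects while EEG analyses apply the
inclusion rule, as in the study design.  Every stochastic stage draws from
a seed tree rooted at the single master seed, making runs byte-identical;
the manifest records the config hash, seeds, and montage hash needed to
re-execute a run.  There is no stage caching: a full default run takes
under a minute, so deterministic re-execution is simpler and safer than
content-addressed caches.

Degenerate inputs are errors, not silent defaults: empty clusters for
correlation, windows outside the epoch, double baseline correction,
zero-variance correlation inputs, and sub-minimum permutation counts
(n_perm < 100) all raise `ValidationError`.

## Known limitations

- The synthetic generator's amplitudes and noise levels are fixture
  choices; absolute µV scales carry no empirical claim.
- The subject gain couples both windows, so a strength coupling planted on
  the early component also induces a (sign-flipped) late-window
  correlation in synthetic cohorts.
- BrainVision support covers the multiplexed float32/int16 dialects only;
  vectorized orientation is rejected explicitly.
- No ocular regression/ICA, channel interpolation, or source localization;
  the sensor-space analysis is the scope.
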