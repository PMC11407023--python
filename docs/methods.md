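# Methods

## The analysis problem

Two players hear the same auditory cue and each waits what they believe is the
cued interval ("short", "medium", "long") before pressing a button; the
attempt succeeds when the presses fall within 250 ms (inclusive) of each
other, and both players then see the same feedback. Because the only channel
for converging on a shared interval representation is this feedback, the
post-feedback brain response — in particular frontal-midline theta (4–7 Hz),
the classic marker of feedback processing and behavioral adjustment — is the
natural place to look for signatures of *joint* strategy adjustment. The
pipeline quantifies, for every pair, how the two players' single-trial theta
power covaries across failed trials, and whether that covariation differs
between failed trials that precede another failure and failed trials that
precede a success.

## Synthetic dyad generator

The generator is the package's study stand-in: it produces data with exactly
the statistical structure the analysis assumes, so every downstream claim can
be tested against known ground truth.

**Behavior.** Each player holds an internal mean μ_c per cue condition,
initialized as `interval_means[c] · (1 + initial_spread · N(0,1))`
(interval means 1, 2, 3 s). Responses are Weber-scaled:
RT ~ N(μ_c, weber_fraction · μ_c), floored at 50 ms — scalar timing, so
longer intervals are noisier and accuracy falls from short to long. After
failed feedback the slower player lowers and the faster player raises μ_c by
`learning_rate · |ΔRT|`, the simplest convergent dynamic; nothing in the task
description fixes a particular update rule, so this is an explicit modeling
choice, exposed in `SimConfig`. Trials come in 10 blocks of 30 with 10 trials
per condition per block, shuffled uniformly within block. Defaults
(weber_fraction 0.12, initial_spread 0.15, learning_rate 0.3) were fixed once
so the simulated accuracy profile falls near the published task's operating
point (≈ 79 / 49 / 32 % for short/medium/long at the defaults, overall
≈ 52 %); pure Weber scaling cannot produce a long-condition accuracy as high
as a real adapting participant while keeping the short condition realistic,
a known gap between the stand-in and real behavior.

**EEG.** Epochs are built at the epoched stage (preprocessing is assumed
done): per trial and channel, 1/f^1 background noise (per-channel std 10
a.u.), spatially mixed across channels with a variance-preserving Gaussian
distance kernel (width 0.5 on the unit sphere) to give realistic channel
covariance. On top of the noise:

* a **theta burst**: a Hanning-windowed 6 Hz sinusoid in the 0–0.4 s
  post-feedback window, weighted by a fronto-central scalp Gaussian centered
  at the FCz site. Trial-wise amplitudes are lognormal (median 15, shape 0.4
  — power is non-negative and right-skewed), with the *mean* 1.5× larger
  after failed than after successful feedback.
* **amplitude coupling**: the two players' burst amplitudes are drawn from a
  Gaussian copula whose Pearson parameter is r = 2 sin(πρ_S/6) — exact for
  bivariate-normal ranks — so the pair's amplitudes have Spearman correlation
  ρ_S by construction. ρ_S is `coupling_rho_fail` (+0.5 default) when the
  *next* trial fails and `coupling_rho_success` (−0.5 default) when it
  succeeds; the assumption that burst amplitude tracks the need for
  representation adjustment is a modeling postulate, not an observed
  mechanism.
* a **beta boost**: a 20 Hz windowed sinusoid (0.2–1.0 s, amplitude 5) over
  centro-posterior sensors on successful trials, emulating post-positive-
  feedback strategy maintenance.

One consequence worth knowing: because the failed-feedback amplitude gain is
shared by both players, band power pooled across outcomes is positively
correlated between players even at ρ_S = 0. Independence (and the copula
calibration) holds *within* an outcome stratum — which is also the stratum
every coupling analysis operates in, since only failed trials are sorted and
correlated.

**What the generator does not emulate:** artifacts (blinks, line noise,
channel dropout), volume-conducted source geometry, non-stationary
oscillatory backgrounds, phase coupling between players, continuous
(non-epoched) recordings. Passing tests therefore validate the *analysis
machinery* and its calibration, not claims about real recordings.

## Time-frequency decomposition

Sliding Hanning tapers with an adaptive window of 3 cycles per frequency
(full study grid 2–50 Hz × −1 to 4.8 s in 0.05 s steps; 500 Hz sampling).
Numerical choices:

* window length = `round(cycles/f · sfreq)` to the nearest **odd** sample
  count (ties upward) so the taper centers symmetrically on the time point;
* the taper is normalized by its **sum** (coherent gain). With adaptive
  window lengths an RMS normalization would make own-frequency response grow
  as the window shrinks (≈1/f²), letting a neighboring lower frequency
  out-score a pure tone's own frequency; coherent-gain normalization is
  amplitude-calibrated across frequencies and makes a unit sinusoid peak at
  its own frequency. Relative baseline correction cancels any fixed
  per-frequency convention, so downstream contrasts are unaffected;
* points whose full window would cross an epoch edge are **masked** (NaN and
  flagged), never extrapolated, and masked points are excluded from every
  downstream average and statistic;
* power is computed in double precision and stored float32 by default
  (`dtype=float64` available where full precision matters).

Baseline correction is (P − B)/B with B the mean power in −0.6 to −0.1 s —
per trial by default, because the coupling and trial-by-trial regressions
need trial-resolved values; a per-average mode exists for grand-average maps.
A zero baseline raises an explicit degenerate-baseline error.

## Inter-player coupling

At each (channel, frequency, time) point the Spearman correlation is computed
**across trials** between the two players' power, using mid-ranks for ties,
then Fisher-transformed (atanh, with |ρ| clipped to 1 − 1e−7) so maps from
pairs with different trial counts can be averaged and contrasted. Points with
constant power across trials are undefined and propagate as NaN. Coupling is
computed on **raw** single-trial power by default: rank correlation across
trials is not invariant to per-trial normalization, so baseline-corrected
coupling is a genuinely different estimand and is available as an explicit
mode (`coupling_input: relchange`). Pairs contributing fewer than
`min_trials` (default 10) trials to a forecast condition are dropped and
logged; the study data this mirrors had ~46–49 trials per condition.

## Cluster-based permutation inference

Sensor adjacency: electrode positions are azimuthal-equidistant projected to
2-D, Delaunay-triangulated, and edges longer than 1.5× the median edge length
pruned; degenerate geometries fall back to symmetrized 4-nearest-neighbors
with a warning. Under the packaged 32-channel 10-20 montage Fz and FC2 are
neighbors.

The paired contrast computes per-point dependent-samples t values (frequency
dimension removed by band averaging first), thresholds two-sided at the
α = .05 Student-t quantile, clusters supra-threshold points over sensor
neighborhood and consecutive time bins separately per sign, discards clusters
whose spatial footprint spans fewer than 2 channels, and scores each cluster
by its summed t. The null distribution is the maximum |cluster sum| under
within-unit condition swaps (sign flips of the paired differences): 1000
permutations by default (500 in the test profile), exact enumeration when
2^n_units ≤ n_perm, and the positive-biased estimator
p = (b + 1)/(n_perm + 1), which never returns 0. Zero-variance points get
±∞ t with a flag; points undefined in any unit are excluded from observed
and null maps alike. The generator seed and permutation seed are recorded in
every result for exact reruns.

Named analysis windows ship as configuration because the source analyses used
several: `theta_predefined` 0–0.4 s, `theta_predefined_late` 0.6–1.05 s,
`alpha_predefined_methods` 0.4–1.65 s, `alpha_predefined_results`
0.3–1.75 s, `exploratory_0_2` 0–2 s, `full_0_4` 0–4 s. None is privileged;
the coupling default is `theta_predefined`. Windows are clipped to the
available time axis on reduced grids.

## Behavioral statistics

* Outcome: success iff |RT₁ − RT₂| ≤ 250 ms, boundary inclusive.
* Behavioral adjustment: RT of the nearest *preceding* same-condition trial
  minus the current RT (positive = speeding up across repeats); the first
  occurrence of each condition is undefined. The sign convention follows the
  definition verbatim.
* Speed-direction split (failed trials only): the player who pressed second
  must speed up, the one who pressed first must slow down; an exact tie is
  impossible on a failed trial since |Δ| > threshold > 0.
* Adjusters: median split on per-player RT standard deviation; values at or
  below the median (including exact ties) are non-adjusters — the split
  needed a tie rule and ties-low keeps the adjuster group strictly above the
  median.
* Regressions are ordinary least squares (statsmodels) with explicit
  rank-deficiency errors; the interaction model is
  y ~ 1 + x1 + x2 + x1·x2 (+ covariate). The adherence check replaces a
  mixed-effects RT model with a fixed-effects fit on condition plus pair
  indicators, reporting the three pairwise condition contrasts — random
  effects estimation is out of scope, and the check's purpose is directional
  (RT ordering short < medium < long), not coefficient reproduction. The
  regression target for "cooperative outcome" is |ΔRT| in seconds.

## Problem sizes and the test profile

The full study grid (49 frequencies × 117 time points × 32 channels × 300
trials × 29 pairs) is configurable but not what the tests run. The packaged
test profile uses short epochs (−1.3 to 1.5 s, or −0.8 to 0.8 s where no
baseline is needed), a theta-only 4–7 Hz grid in 0.1 s steps, ≤ 60 trials
per forecast condition, and 200–500 permutations; the end-to-end recovery
checks use 25 pairs × 20 seeds. These sizes are the package's chosen
operating point for routine verification; all of them scale up by
configuration only.

## Known limitations

* The behavioral agent is a two-parameter convergent learner; it reproduces
  accuracy *ordering* across conditions, not any specific participant's
  adaptation trajectory or the full published accuracy magnitudes.
* Coupling is amplitude-based (rank correlation of power); phase-based
  inter-brain measures and directed (leader/follower) measures are out of
  scope.
* Cluster inference operates on band-averaged channel × time maps; joint
  3-D channel × frequency × time clustering and TFCE are not implemented.
* The Fisher-Z mean over a cluster attenuates toward zero relative to the
  planted copula correlation because single-point power carries noise; the
  sign and contrast, not the absolute Z magnitude, are the calibrated
  quantities.
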