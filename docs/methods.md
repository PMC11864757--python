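# Methods

## Scope and data model

One *session* is a bundle of: a uniformly sampled pose table (seven
bodyparts, arena cm), sorted spike-timestamp lists per unit, a trial/event
table, and per-port lick events.  All times are seconds from session start;
positions are cm with the origin at the waiting corner and x toward the
right reward corner, so every downstream quantity lives in a single metric
frame.  The on-disk format is plain CSV plus a JSON manifest (times at
1e-6 s, positions at 1e-4 cm); identical bundles serialize to identical
bytes, which is what makes end-to-end byte-reproducibility testable.

Default frame rate is 60 Hz (typical for bottom-up behavioral video) and
default arena side 35 cm; both live in the session metadata and are
configurable.  The angular-velocity sign convention is positive =
counter-clockwise viewed from below (leftward turn).

## Synthetic sessions

The generator emulates the study conditions rather than any particular
recording.  Per trial: a Return trajectory to the waiting corner, a wait
drawn from U(0.8, 1.3) s, a 0.5 s frequency sweep from the symmetric set
{0, ±0.4, ±0.6, ±0.8} octaves (±0.2 omitted from the default set, as it
was dropped from sessions to increase trials per condition), a 150° turn,
a Go trajectory to the chosen port, and a 2.5 s evaluation with a lick
bout.  False-alarm trials (default rate 0.08) replicate the full motor
sequence without a stimulus, with the turn beginning 0.8–1.1 s after
corner arrival.

Trajectories are straight minimum-jerk paths between halt points pulled
slightly inside the corners (so the head marker stays within the arena
bounds); the heading is carried by the head–tail body axis and performs the
150° turn as a minimum-jerk rotation, with the 75° midpoint landing exactly
halfway through the turn.  Segment durations are Gaussian
(Return 1.8 ± 0.15 s, Go 1.3 ± 0.10 s, turn 0.4 s) snapped to the frame
grid, so all ground-truth events are frame-aligned.  Paw markers carry a
gait oscillation (default 4.5 Hz, hindpaw amplitude 1.2 cm > forepaw
0.8 cm) gated by body speed; licks are emitted at the 7 Hz lick oscillator's
phase-zero crossings, which ties the lick train to the phase ground truth.

Choices follow P(right) = lapse + (1 − 2·lapse)·logistic(slope·(Δ − bias))
with defaults slope 2.5 /octave, bias 0, lapse 0.08 — roughly 80–85%
correct at the easiest stimuli.  Response time is
max(0.15, 0.45 − 0.25·|Δ| + N(0, 0.05)) s.  Zero-octave trials are
rewarded at random, which is also what makes the 2(side) × 4(|Δ|) ×
2(outcome) = 16-cell condition tensor well defined.  The default session
length is 220 trials: condition cells for incorrect responses to easy
stimuli are intrinsically rare under a steep psychometric, and ~220 trials
is the smallest size at which the ≥2-trials-per-cell inclusion rule is
usually satisfiable (sessions in the source experiments were selected for
more than 220 trials for the same reason).

Spikes are inhomogeneous Poisson with the log-link rate

    rate(t) = exp( b0 + Σ_ctx 1[ctx](t) · β_ctx · z(x(t)) + reward(t)
                   + κ_g cos(φ_gait − μ_g)·1[moving] + κ_l cos(φ_lick − μ_l)·1[licking] )

where z(·) uses fixed normalization constants per variable and saturates at
|z| ≤ 2.5 (saturating tuning).  Reward responses are ±amp log-units in a
0.25 s box after port entry on rewarded trials.  Per-unit parameters are
drawn with stratified class counts (reward-positive 40%, reward-negative
20%, context-switching 30% with sign-flipped Go coefficients, phase-locked
60%), and coefficient budgets/clips guarantee a worst-case peak rate below
the 200 Hz bound (raising the bound relaxes the baseline clip accordingly).
Spike times come from Poisson thinning on a 10× oversampled grid.
Everything is deterministic given (config, seed), with per-unit child seeds
spawned from a `SeedSequence`.

What the generator does *not* emulate: tracking artifacts and identity
swaps, non-stationary motivation, port re-entries, variable gait frequency
with speed, bursting/refractory spike statistics, and cross-unit noise
correlations.  Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated generative model, not robustness to
every pathology of real pose-tracked electrophysiology.

## Event detection

Detection uses only hardware observables (stimulus onset, lickometer
head-entry times) plus kinematics: return start is the onset of sustained
(3-frame) movement toward the waiting corner, backtracked to the last frame
with corner-velocity above −0.02 cm/s; wait arrival is the first frame with
corner distance < 1.5 cm (the published pixel threshold is unit-ambiguous,
so a metric default is used); turn start is the first sustained crossing of
the 0.01 deg/s angular-velocity threshold, searched after stimulus onset
(or 0.75 s after wait arrival on no-stimulus trials); turn mid/end are the
cumulative 75°/149.25° crossings of the raw heading.  The angular-velocity
threshold is applied to *raw* centered differences with a persistence
requirement rather than to the Gaussian-smoothed trace: kernel smoothing
leaks the turn into the two preceding frames and displaces the detected
onset even on noiseless data, while the 3-frame persistence supplies the
noise robustness the smoothing was meant to provide.  Derived kinematic
variables (speeds, angular velocity, acceleration) do use positions
smoothed with a σ = 2-frame Gaussian.

## PETHs and the condition tensor

Single-trial rates are Gaussian-kernel estimates (σ = 25 ms, kernel
integrating to 1, truncated at 6σ).  The tensor window runs from 0.3 s
before turn start to 2.5 s after port entry, split at turn start, turn end
and port entry; each trial is warped onto the session-mean segment
durations by a piecewise-linear time map (landmarks map exactly; constants
are invariant; spike count is conserved up to the duration ratio).  The
canonical grid step is 10 ms, comfortably finer than the 25 ms kernel.
Units need at least two trials in each of the 16 condition cells; excluded
units are listed on the tensor.  Rates in Hz feed the variance analyses;
per-unit z-scores (over all condition × time entries; zero-variance units
flagged, not divided) feed dimensionality reduction — z-units are the
default for demixed PCA.

## Population geometry

Instantaneous marginal variance, cosine self-similarity and PCA follow the
formulas quoted in the README; all are tested against brute-force
double-loop implementations at 1e-10.

Demixed PCA is implemented as described by its construction: the centered
tensor is decomposed ANOVA-style into a condition-independent (time) part,
per-factor parts (factor-conditioned means minus the time part, i.e. each
factor term carries its interaction with time), and a residual holding all
factor × factor interactions.  In this balanced design the parts are
mutually orthogonal, so the decomposition reconstructs the tensor exactly
and part variances sum to the total — both asserted at 1e-10.  Each part's
unit × unit covariance is eigendecomposed, components are reported by
explained total variance (ETV = part eigenvalue / total variance), and the
full centered data are projected onto the demixed axes.  This is the
"PCA on marginalized covariances" variant, not the regularized
reference implementation; parity with that package is out of scope, and
the decomposition identity serves as the correctness anchor.

Eigenvalue significance compares each rank against per-unit time-shuffled
tensors (default: circular rotation by an independent uniform offset per
unit, preserving autocorrelation; plain permutation available — note that
rotation nulls retain power only against aperiodic structure, a periodic
shared signal survives rotation).  Rank k is significant when its
eigenvalue exceeds the (1 − α) null quantile of rank-k eigenvalues, applied
contiguously from the first rank.

Trajectory matching builds per-side Go model profiles (body speed and
angular velocity, resampled to 50 points, averaged over trials) and selects
Return and Go trials whose per-variable-standardized profile correlates
≥ 0.75 with the side-matched model.  The Go displacement window is turn end
→ port entry (the turn itself excluded, so Return and Go displacements are
kinematically comparable); a Return trial's side is the port it returns
from.  Matched trials form the units × context × side × time tensor for the
context marginalization.

## Encoding models

Designs tile the Return/Wait/Go/Evaluation periods with 0.2 s windows every
50 ms; predictors are interpolated at window centers and the target is the
window-mean smoothed rate.  Families: kinematic {body speed, head speed,
angular velocity, acceleration}, spatio-temporal {distance to goal,
distance to waiting corner, velocity from waiting corner, elapsed trial
fraction}, reward-related {reward indicator (0.5 s box from port entry on
rewarded trials), lick rate (Gaussian σ = 50 ms), port-entry kernel}.
"Elapsed fraction" stands in for time-in-trajectory among the
spatio-temporal variables.

Fits are LASSO with 10 outer folds (grouped by trial); the penalty is
chosen by inner 5-fold cross-validation on the training folds (minimum-CV
λ, no one-standard-error rule), with columns standardized inside each
training fold; cvR² is the mean held-out R² (can be negative).  Transfer
R² scores the frozen pipeline (training-context standardization and
penalty) on the other context's rows.  Partial correlation regresses the
rate on a reduced OLS model and correlates the residuals with the held-out
variable; reduced sets follow fixed rules (distance-to-goal: kinematic
covariates only; angular velocity: everything but itself; body speed:
everything but itself and head speed).  ΔR² refits the model with one
variable's values shuffled (same folds), so information shared with
collinear regressors is not charged to the variable.  All permutation
p-values use the add-one estimator (1 + #exceed)/(1 + n), which is valid
and never zero.

Reward sensitivity is the auROC of per-trial spike counts in the 250 ms
after port entry, rewarded vs incorrect trials, computed in the rank
(Mann–Whitney) form with average ranks for ties; significance is a
two-sided label permutation on |auROC − 0.5| (default n = 1000, so the
attainable floor 1/1001 sits below the 0.001 class threshold).

## Rhythmic coupling

Strides are peaks of the contralateral hindpaw position projected on the
body axis (minimum inter-peak interval one period of the 6 Hz band top,
prominence 25% of the segment range; trajectories with < 4 strides are
excluded).  Phase comes from a 4th-order zero-phase Butterworth band-pass
(gait 3–6 Hz, lick 4–10 Hz) followed by the analytic-signal angle, so phase
0 sits at signal peaks.  Spike phases are pooled in 0.4 s windows around
events (≈ two cycles); the mean resultant vector is tested with the
Rayleigh approximation p = exp(√(1 + 4n + 4(n² − Rn²)) − (1 + 2n)),
cross-checked in tests against an independent implementation and a
Monte-Carlo exact null at small n.  Lick bouts split at inter-lick gaps
> 0.5 s (≫ the ~0.14 s lick period) with ≥ 3 licks; the lick-rate
correlation rescales each bout to the mean bout duration and uses circular
rotations of the rate trace as the null (computed for all shifts at once
via FFT), which preserves autocorrelation and avoids the anti-conservative
behavior of i.i.d. shuffling on smooth traces.  Population summaries
average per-unit vector components (x, y) and report the fraction of units
with Rayleigh p < 0.001.

## Decoding

Linear SVCs (fixed C = 1; tuning would break the exchangeability of the
permutation null) with 10-fold cross-validation, grouped so that no
trajectory or bout contributes to both training and test folds — the
grouped default also avoids the twin-leakage anti-learning artifact that
plain folds exhibit on duplicated rows.  Continuous labels are discretized
into five quantile states by rank (class counts equal ± 1).  Null
distributions permute labels (within the grouping structure when groups are
label-pure); p is the add-one estimate.  Per-unit standardization is off by
default: inputs are typically already z-scored, and the eigenvector-weighted
matrix used to expose signals in low-variance population modes would be
undone by per-feature standardization (the rescaling-invariance property is
asserted with standardization explicitly on).

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small problem
sizes chosen as the smallest at which each statistical claim is stable:
10-unit tensors for exact oracles, 60 units for factor recovery, 100–200
replicates for calibration checks, 60-trial/6-unit sessions for reward
recovery (with a ~90 Hz pallidal-like baseline so a 1 log-unit suppression
is ~3× the Poisson count noise), and a 120-trial/30-unit session for the
end-to-end pipeline benchmark.  The reported pipeline runtime and
byte-reproducibility are measured on exactly those sizes.  Degenerate
inputs are flagged rather than propagated: constant targets, zero-variance
units, zero-norm population vectors, underpowered comparisons (< 6 units),
and trials with unordered or missing detections are excluded with a record.

## Known limitations

* The published population numbers (component ETVs, fractions of modulated
  units, n = 118) derive from the real multi-animal recordings and are not
  reproducible from synthetic sessions; the package's claims are
  correctness and calibration, verified by oracles and parameter recovery.
* The demixed-PCA variant here has no decoder/encoder regularization, so
  axes within different marginalizations are not forced toward
  orthogonality across marginalizations.
* Rotation-based significance shuffles are conservative for periodic
  signals (see above); choose the permutation shuffle for stride- or
  lick-locked tensors.
* The generator's straight-path, frame-aligned behavior makes event
  recovery essentially exact; on real tracking the detection thresholds
  (arrival distance, angular-velocity persistence) would need tuning
  against labeled videos.
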