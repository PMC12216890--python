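# Methods

`gaitspace` implements a subspace-level analysis of multi-region neural
population recordings during repeated gait cycles across several locomotor
tasks, together with a synthetic-session generator that plants the latent
structure the analysis is supposed to recover.  This note documents the
models, the defaults and why they are what they are, the numerical choices,
and what the synthetic validation does and does not show about real data.

## Pre-processing model

Firing rates are estimated by counting spikes in sliding 10 ms windows
advanced in 0.5 ms steps (a 2 kHz estimate in Hz), smoothing with a
Gaussian kernel of 50 ms standard deviation, z-scoring each channel over
the whole session, and decimating to 1 kHz by keeping every second sample
(the smoothing already band-limits, so no extra anti-alias filter is
applied).  Channels with zero variance are flagged and carried as zeros:
they stay in containers so shapes never silently change, but every
analysis excludes them.

A gait cycle is the epoch between two consecutive foot strikes; stance
runs from foot strike to foot off.  Cycles are rejected when the total
duration exceeds 1.5 s, then — among the survivors, per task, because
tasks have different duration distributions — when the stance duration
falls outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`.  Surviving cycles are warped
by linear interpolation onto a 100-sample phase grid: stance to samples
0–59, swing to samples 60–99 (0-based; circular arithmetic modulo 100;
degrees = phase × 3.6).  Linear interpolation cannot create new extrema,
so warping preserves each cycle's peak rate and modulation depth.

Per-channel summaries: modulation depth is max − min of the trial-averaged
peri-gait rate; the preferred gait phase (PGP) is the argmax sample treated
as a circular variable of period 100 (ties resolved to the smallest
index); the PGP spread across tasks is the circular standard deviation in
the angular-deviation form `sqrt(2(1 − R̄))`, reported in degrees.  The
log form `sqrt(−2 ln R̄)` is available as an option; the angular-deviation
form is the default because its chance level for five uniform angles
(~61.7°) is the magnitude a chance-level spread statistic of this kind
should have, whereas the log form is far larger (~80°) and unbounded.
The cross-task correlation averages Pearson correlations between warped
single-cycle traces in a fixed order: cycle pairs → task combination →
channels → combinations, excluding self-paired tasks.

## Manifolds and the alignment index

A dataset's manifold is the span of its leading principal components; the
dimensionality `d` is the smallest number of components whose cumulative
variance strictly exceeds a threshold (default 90%, configurable).  A
`1e-9` guard is added to the strict comparison so constructions that land
exactly on the threshold (equal-variance planted components) resolve
deterministically to "not exceeded" rather than by floating-point
summation order.  PCA runs on single-cycle warped activity concatenated
over cycles rather than on trial averages, because the dimensionality
ceiling argument (task duration / smoothing width, e.g. 942 ms / 128 ms ≈
7.4) reasons about single-cycle activity.  Region comparisons subsample a
fixed number of channels (default 32) over seeded repetitions (default
1000, with 2000 available) and report means.

The alignment index of task *a* against task *b* is the variance of *a*'s
trial-averaged activity captured in *b*'s m-dimensional manifold divided
by the variance captured in *a*'s own m-dimensional manifold, both through
the reconstruction-error form `(‖X‖² − ‖X − D_m E_m X‖²)/‖X‖²`.  A single
`m` is used for numerator and denominator — by default the larger of the
two tasks' 90% dimensionalities — because the ratio is only a calibrated
fraction when both projections have the same rank; a caller can fix any
`m`.  The session statistic is the mean over all 20 ordered task pairs.

## Demixed PCA (two marginalizations)

The centered trial-averaged tensor X (channels × tasks × 100) splits into
a task-independent part `X_TI` (the across-task mean, replicated) and a
task-dependent remainder `X_TD = X − X_TI`.  Only these two
marginalizations are used — gait phase and task are the only two behavioral
parameters — rather than the four-way split of generic two-factor demixed
PCA.  The split is exactly orthogonal (`‖X‖² = ‖X_TI‖² + ‖X_TD‖²`), and
for *any* rank-1 readout the part-wise explained variances add to the
total; per-mode TI% + TD% = total% is therefore an identity, not an
approximation.

Each marginalization is fit in closed form: ridge regression of `X_m` on
X (`μ` defaults to `1e-6·‖X‖²/n`; trial averages are well-conditioned, so
cross-validated regularization is not implemented), followed by projection
onto the leading left singular vectors of the fitted prediction.  Decoder
axes are normalized to unit length and encoder axes solve the least-squares
reconstruction; with `μ → 0` and a planted full-rank toy this reproduces
the truncated-SVD optimum of each marginalization exactly (the test suite
asserts agreement to 1e-8 against a brute-force SVD oracle).  Ten modes per
marginalization are extracted by default, pooled, and ordered by total
explained variance.  A mode is task-independent when more than half of its
variance is accounted for by the TI part.  Mode removal subtracts
`Σ f_j d_jᵀ X` from the full-resolution (per-channel-centered) rate matrix
and reports the variance fraction removed, so decoding-after-removal
results can be read against removed variance.

In the variance table, per-mode percentages are each mode's own explained
variance as defined above; their cross-terms are not exactly zero across
marginalizations, so the table reports the remainder to 100% as
"unassigned" and, separately, the joint residual of the pooled
reconstruction (the quantity mode removal reproduces).

## Communication subspaces

For one task, samples are the concatenated 100-sample warped cycles.  The
target region Y is regressed on the source region X with ridge regression
`B = (XᵀX + λI)⁻¹XᵀY`; λ is chosen on a 20-point log grid spanning
`10⁻⁴–10⁴` times the mean diagonal of XᵀX by 10-fold cross-validation
whose folds are contiguous blocks of whole gait cycles (random samples
would leak the strong within-cycle autocorrelation), using the
one-standard-error rule: the largest λ whose mean pooled R² is within one
SE of the best.  R² is the variance-weighted multi-output form
`1 − Var(Y − Ŷ)/Var(Y)`.

The rank is then restricted: V holds the principal directions of the ridge
prediction, `B(m) = B_ridge V_m V_mᵀ`, and `m_RRR` is the smallest m whose
prediction explains at least 95% of the variance the full ridge prediction
explains.  The first `m_RRR` columns of `B̄ = B_ridge V` are orthonormalized
(SVD) into the source-space communication basis — orthonormalization is
done before any principal-angle computation because `B̄`'s conditioning is
otherwise arbitrary.  Note the 95% rule recovers a planted rank only when
the planted components carry comparable variance; a component below ~5% of
the explained variance is truncated by definition.

## Principal angles, Δangles, and nulls

Principal angles between orthonormal bases are the arccos of the singular
values of `W_aᵀW_b`, clipped to [0°, 90°], ascending.  The Δangles
statistic is the mean of the five communication-to-task-dependent angles
minus the mean of the five communication-to-task-independent angles, the
TD/TI subspaces being built from exactly the five leading modes of each
label; positive values mean the communication subspace is aligned with the
task-independent subspace.

Null distributions: cycle bootstraps that resample one task's cycles with
replacement into two (or five) pseudo-datasets presented as pseudo-tasks
— the noise-floor construction for correlation/alignment (split) and
PGP-spread/TI-variance (five); circular phase shuffles that advance every
(channel, cycle) trace by an independent uniform shift (chance for any
phase-locked statistic, and — applied to the target region before
refitting — the noise floor for Δangles); five uniform angles for the PGP
chance level; and Haar-random subspaces (orthonormalized Gaussian
matrices) for principal-angle chance.  P-values use the one-sided
Monte-Carlo add-one convention `p = (1 + #extreme)/(1 + N)`, whose floor
at N = 2000 is 1/2001 ≈ 0.0005.  Whether a chance level's "±" is the null
standard deviation or its standard error is reported both ways in
`StatResult.summary()`.

## Decoders

Gait-event detection uses a three-class regularized LDA (foot strike,
foot off, none; scikit-learn's `lsqr` solver with shrinkage).  Features
are per-channel rates binned into B bins over the L ms preceding an event;
"none" exemplars sit at midpoints between consecutive events.  (L, B,
shrinkage) are selected by stratified cross-validation on the calibration
task (grids default to L ∈ {100..500} ms, B ∈ {5, 10}, a log shrinkage
grid; ties prefer shorter windows, then fewer bins, then stronger
regularization), and the final model is refit on the whole calibration
task.  At run time the posterior is evaluated every 10 ms; an upward
crossing of the 80% threshold is a detection, same-class detections within
100 ms are suppressed, and detections are scored by greedy matching to the
nearest unmatched true event within ±125 ms (the matching window is a
scoring choice, configurable).  The F-score is the mean over the two event
classes of `2PR/(P + R)`.

Task classification from per-cycle behavioral features uses the same rLDA
with 5-fold cross-validation, reporting mean accuracy and the pooled
confusion matrix.  EMG envelopes and kinematics are reconstructed with a
Wiener filter over lagged rates (10 ms lag spacing; 100 ms window for EMG,
300 ms for kinematics), ridge-regularized with λ from 5-fold
contiguous-block cross-validation on the calibration task; an optional
static polynomial stage (default off, i.e. degree 1) makes it a Wiener
cascade.  Velocities come from a first-derivative Savitzky-Golay filter.

## Synthetic sessions: what is planted and how

Latent trajectories are smooth periodic functions on the 100-sample phase
grid built from random Fourier series.  TI trajectories (orthonormal rows,
zero phase-mean) are identical in every task.  TD trajectories rotate a
private pair of waveforms across tasks,
`z_j(t) ∝ cos(2πt/T + φ_j)·g_{2j} + sin(·)·g_{2j+1}`, with the g's
orthonormal and orthogonal to the TI span of the function space.  This
construction gives, simultaneously: zero mean across tasks at every phase
(so the TI/TD marginalization recovers the planted split exactly and
variance fractions are additive), orthonormal task-concatenations, and —
within every single task — TD time courses that are mutually orthogonal,
orthogonal to the TI courses, and of equal energy.  The last property is
what makes single-task fits well-posed: with a small harmonic budget a
task's TD courses would be linear functions of the TI courses and no
single-task regression could tell a TI-reading communication map from a
TD-reading one.  This requires `n_ti + 2·n_td ≤ 2·harmonic_order`
(validated); the default harmonic order is 8.

Channel loadings come from a real-Fourier orthogonal basis whose TI and TD
blocks are assembled from whole cos/sin pairs (plus the constant/Nyquist
columns for odd counts) and rotated randomly within each block.  Every
channel then carries exactly the same signal variance and the same TI/TD
split, so the per-channel z-scoring in pre-processing is a uniform
rescaling and planted variance fractions survive the pipeline exactly —
with Haar-random loadings they would be distorted by a few points at 64
channels.  Amplitudes are set analytically so the noiseless signal has
per-channel RMS `gain` and the configured TI fraction.

Cycle durations are truncated-normal (0.3–1.5 s; default mean 0.94 s,
matching the recording regime the generator emulates), stance fractions
normal around 0.60 (s.d. 0.03), and the latent phase is mapped into real
time per cycle before any warping, so the warping step is exercised
nontrivially.  White Gaussian rate noise (default 2 Hz per 1 kHz sample
against an 8 Hz signal RMS) is added; Poisson spike emission is optional
and off by default so tests are fast and noise-controlled — single-trial
noise magnitudes of real multiunit recordings vary widely, so the default
is chosen as a realistic low-noise regime for threshold-crossing
multiunits, not fit to any dataset.

The communication target region is `Y = S B_true + noise` where S is the
noiseless centered source signal and `B_true = U_in G V_outᵀ` has known
rank; `U_in`'s columns interpolate between random orthonormal directions
inside the planted TI span (α = 1) and the TD span (α = 0), and G scales
each component to a common RMS over the session.  EMG envelopes are
rectified linear readouts of the latents with positive baselines;
kinematics are linear readouts of 4 landmarks × (x, y, z), referenced to
the across-landmark mean per coordinate.

What the generator does *not* emulate: spiking non-Poissonianity, slow
nonstationarity and electrode drift, cross-channel correlated noise,
behavioral variability beyond duration/stance jitter, nonlinear
latent-to-rate links, and inter-region dynamics beyond a static linear
map.  Passing recovery tests therefore show the estimators are correct and
well-calibrated under their own assumptions — not that real cortical data
satisfies those assumptions.

## Problem sizes used in the shipped checks

The recovery battery runs 20 sessions at 64 channels, 5 tasks × 100
cycles, noise 0.5 Hz, with planted communication ranks cycling 1–6 and
alignment alternating between 0 and 1; the same sessions serve the TI
variance (68 ± 3 points), rank-recovery (≥ 95% of seeds), and
Δangles-sign (all seeds) checks.  The decoding protocol uses a 32-channel,
5-task × 25-cycle session with a 95%-TI code.  The demo pipeline defaults
(`cli_io.PIPELINE_DEFAULTS`) use 100 subsample repetitions and 200 null
draws; all repetition counts are parameters.

## Known limitations

* The figure commonly quoted for the five-uniform-angle chance level
  (60.33°, from circular-statistics toolboxes whose exact convention is
  unstated) differs by ~2% from the exact Monte-Carlo expectation of the
  angular-deviation procedure (61.66 ± 11.33 over 2M draws); the value is
  reported as computed.
* The per-mode variance table's "unassigned" remainder conflates residual
  variance with cross-marginalization interference of the pooled modes;
  the joint residual is reported separately.
* `m_RRR` recovery presumes balanced planted components (see above); this
  is a property of the 95% rule, not of the implementation.
* The event decoder's matching window (±125 ms) and posterior step (10 ms)
  are scoring conventions; F-scores are comparable only at fixed values.
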