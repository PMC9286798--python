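# Methods

`middecode` re-implements, as a tested and reusable pipeline, a single-trial
multivariate analysis of EEG reward anticipation in the monetary incentive
delay (MID) task: a sliding-window regularized Fisher discriminant with
leave-one-out performance (Az), permutation-based significance, forward-model
scalp maps, reaction-time-matched salience contrasts, a single-trial
variability (STV) to RT regression with a group-level test, and classical
ERP window measures with a cluster-permutation group comparison. Because no
public recordings accompany the original study, the package ships a task and
EEG simulator whose planted structure matches what the downstream analysis
assumes; all tests run end-to-end on simulated cohorts.

## Task simulation

Each trial presents a gain, loss or neutral cue (250 ms), a jittered
2000-2500 ms anticipation delay, a speeded target whose response interval is
controlled by an adaptive staircase, a 1200 ms blank, 1000 ms feedback and a
2000 ms inter-trial interval. A session has 48 trials per condition
(144 total) in randomized order, preceded by 30 practice trials.

The staircase runs per condition on the running success rate: after every
trial of a condition, the target duration is shortened by one step if the
cumulative hit rate of that condition exceeds the 66% design target and
lengthened if it falls below, clipped to 100-1250 ms. The step size (25 ms)
and initial duration (500 ms) are free design parameters not fixed by the
task description; the practice block carries its final durations into the
main block while the running-rate counters restart, so the staircase
regulates the main block's own hit rate. Because the controller regulates
the cumulative rate directly, the achieved hit rate converges to the target
for any agent whose RT distribution overlaps the duration bounds; simulated
cohorts land within about one percentage point of 66%.

The simulated agent draws Gaussian RTs per condition (defaults: gain/loss
280/285 ms, neutral 330 ms, sds 60-70 ms — incentive speeding of ~45 ms,
matching the usual neutral-slower pattern) and lapses (no response) on 2% of
trials. A hit is an RT at or under the current target duration; outcomes are
coded +1/-1.

## EEG generation

Epochs are cue-locked, -500..2000 ms at 256 Hz (641 samples; the sampling
rate is configurable and deliberately below typical acquisition rates to
keep desk-scale runtimes), over the 64-channel 10-10 Biosemi montage
(positions from MNE). Each epoch is

    x_i(t) = a_V(i) topo_V k_V(t) + a_S(i) topo_S k_S(t) + n_i(t)

* Valence component: unit-norm Gaussian spatial pattern peaked at Pz
  (sigma 6 cm), temporal bump centered at 450 ms (sd 60 ms, truncated at
  3 sd). Its amplitude is +g for gain cues, -g for loss cues, plus a
  zero-mean per-trial Gaussian deviation (the planted STV, sd 4 uV).
* Salience component: pattern peaked at FCz, linear ramp from 1300 ms to the
  target time (2000 ms); amplitude is positive on incentive trials and zero
  on neutral trials.
* Noise: spatially correlated Gaussian (random reduced-rank mixing of
  n_channels/2 sources plus a diagonal floor, unit average channel power)
  with a 50/50 temporal mix of white and 1/f noise. The reduced-rank,
  ill-conditioned channel covariance is chosen so covariance shrinkage in
  the discriminant is genuinely beneficial; the 1/f component gives the
  within-window temporal correlation real EEG has.

Group presets: an LA-like group (valence amplitude 10 uV, salience 4 uV,
negative RT link) and an HA-like group (valence amplitude 0, salience 6 uV,
no RT link), differing only in those parameters. Default SNR (amplitudes vs
4 uV noise sd) was fixed once, at design time, so that a default LA-like
participant reaches peak Az near ceiling and forward maps correlate >= 0.95
with the planted topography — the regime the recovery analyses assume; it is
not adjusted per experiment.

When the RT link is enabled, RTs are re-generated from the planted valence
STV, RT = beta0 + beta1*STV + eps (defaults 320 ms, -15 ms/uV, residual sd
60 ms), and outcomes are re-derived against the staircase's target
durations. The causal direction (STV first, RT derived) matches the use of
STV as a regressor for upcoming RTs.

What the generator does not emulate: volume conduction from a head model,
ocular/muscle artifacts, inter-electrode noise structure tied to geometry,
non-stationarity across the session, or feedback-phase activity. Passing
recovery tests therefore demonstrate the pipeline's correctness and
calibration under the planted linear model, not performance on real
recordings.

## Preprocessing

Zero-phase (forward-backward) IIR filters: 0.1-95 Hz 4th-order Butterworth
band-pass, 50 Hz notch (Q = 35), and a final 30 Hz low-pass; common average
reference across scalp channels (idempotent, warns on re-application);
cue-locked epoching with optional baseline subtraction over -200..0 ms (the
baseline window is a convention, applied identically to all trials, and a
configuration flag — the discriminant contrasts trial classes, so a shared
baseline shift is immaterial). An amplitude-threshold epoch rejector stands
in for statistical artifact rejection and is off by default (synthetic data
contain no artifacts). Filters validate cutoffs against Nyquist.

## Sliding-window regularized Fisher discriminant

Training windows are 60 ms wide with centers every 10 ms from -200 to
2000 ms (221 windows; the grid time is treated as the window *center*, with
an onset convention available). Within a window the EEG is averaged over
samples (closed interval on sample centers; 15-16 samples at 256 Hz),
giving one channel vector per trial.

Per-class covariances are shrunk toward the scaled identity,
S~ = (1-lambda) S + lambda (trace(S)/D) I, which preserves the trace;
lambda = 0 is the empirical covariance and lambda = 1 the spherical limit.
The common matrix is the average of the two shrunk covariances and the
weight vector solves S_c w = m2 - m1 (solved in the eigenbasis; eigenvalues
below 1e-10 of the maximum are truncated, giving pseudo-inverse behaviour
with a logged warning when S_c is rank-deficient, e.g. at lambda = 0 after
average referencing). Per-trial component amplitudes are y_i = w'x_i.

Performance is the rank-based AUC (ties counted 1/2) of held-out y values
under trial-level leave-one-out: for each trial the discriminant is refitted
on the remaining trials. Refits are computed exactly via a rank-one
covariance downdate and a Sherman-Morrison solve in the eigenbasis of the
per-class base matrix, so the entire lambda grid shares two
eigendecompositions per window; a from-scratch batched-eigendecomposition
path handles degenerate configurations (near-singular systems fall back
automatically). Windows whose vectors are numerically constant return
all-tied scores (Az 0.5) rather than amplified rounding noise.

Lambda is chosen per window by grid search (0 to 1 in steps of 0.01 by
default) maximizing the LOO Az, ties broken toward stronger shrinkage.
The selection is made on the same trials it is evaluated on; the
permutation null re-runs the identical selection inside every draw, so the
optimism cancels in the significance machinery. The stored per-window
component amplitudes come from the full-data fit at the selected lambda
(deterministic, and the quantity the forward model and STV use); the Az is
always the held-out one.

Degenerate windows (outside the epoch span, or fewer than 2 trials in a
class) yield null records, not exceptions.

## Permutation inference and forward models

The null distribution of the windowed Az re-runs the full pipeline (lambda
grid search plus LOO) on label-permuted trials, 1000 draws by default. The
threshold is the k-th largest null draw with k = floor(alpha n): the
smallest value a strictly greater observation beats with p < alpha. Draws
are pooled across the probe windows into a single threshold by default
(matching the single significance line drawn over Az time courses), with a
per-window mode available; which the original analysis used is not stated,
so both ship. Significant intervals are maximal runs of consecutive
supra-threshold windows, extended half a grid step on each side.

Note on calibration: the *mean* of the null Az sits at 0.5 only for the
exchangeability null at fixed lambda; with the lambda search inside each
draw the null mean shifts above 0.5 by the selection optimism, which is
precisely why the search must be inside the null. Type-I error of the
thresholding procedure is calibrated either way (the tests check the
per-window false-positive rate on no-effect data, whose expected value
under per-window thresholds is exactly alpha; the pooled mode trades
per-window exactness for a single interpretable line).

Forward models map the backward weights to an interpretable scalp pattern,
a = X y / (y'y) (X the channel-by-trial matrix of window-averaged data):
the channel pattern whose coupling to the component amplitudes best
explains the data. Because curves from strong components plateau at their
maximum, the representative peak is the *center* of the near-maximum run
(within 0.02 of the maximum), mirroring midpoint extraction at the time of
maximal discrimination, and the participant-level peak map averages the
per-window maps across that plateau — the same windowed-averaging
convention used for the STV, which suppresses per-window estimation noise
in the map.

## RT matching, STV and the group test

For the salience contrast, incentive trials are matched to the neutral RT
distribution before decoding, removing motor-preparation confounds.
Matching is greedy 1:1 nearest-neighbor pairing on RT (globally closest
pairs first) with a caliper of 0.25 neutral standard deviations, followed
by worst-pair pruning until the standardized mean difference is under 0.1
and the variance ratio lies in [0.8, 1.25]; fewer than 10 surviving pairs
is an explicit failure carrying diagnostics. Equal counts and a
never-increased mean gap hold by construction; identical distributions pair
almost perfectly and retain nearly min(n) trials per side.

The STV is the per-trial mean of the component amplitude over a time
window — for valence, the a-priori 400-550 ms window; when no significant
discrimination exists (the HA-like case) the same a-priori window is used
as the fallback. Per participant, RT is regressed (OLS) on
{1, STV, trial order, trial outcome (+1/-1)}; non-responses are dropped and
counted, and rank-deficient designs fail naming the collinear columns. At
the group level a one-tailed one-sample t test asks whether the
per-participant STV coefficients share the hypothesized sign; the direction
is a configuration parameter recorded in the output (the negative direction
— stronger valence signalling, faster responses — is the planted default).
The two-stage procedure (per-participant OLS, then a t test on
coefficients) is used rather than a joint hierarchical likelihood: the
per-participant equations are fitted independently and only their
coefficients are compared across participants.

## ERP measures and group comparison

ERP components are mean amplitudes over fixed electrode groups and windows:
cue-P3a 250-400 ms and cue-P3b 400-550 ms (P1, P2, POz, Pz), P2 160-210 ms
and N2 210-310 ms (FC1, FC2, FCz, Fz), CNV 1800-2000 ms (C1, C2, Cz, FCz).
The a-priori cue-P3b window and any data-driven significant interval are
distinct outputs and never conflated. Condition and group ANOVAs with
sphericity correction and Tukey post-hocs are thin wrappers over pingouin —
standard statistics, not re-derived. Difference waves are per-channel,
per-sample differences of condition means.

Group Az curves are compared with a nonparametric cluster-mass permutation
test: one-tailed unpaired t per timepoint, threshold at the alpha-level
critical t, cluster mass = summed t over a supra-threshold run, and the
null from maximum cluster masses over random group relabelings (add-one
p-value estimator). This replaces random-field-theory thresholding with a
permutation test targeting the same cluster-level inference.

## Problem sizes and numerical choices

Defaults follow the study design (48 trials per condition, 22 participants
per group, 221-window grid, 101-point lambda grid, 1000 permutation draws).
The test suite runs the same pipeline at desk scale, as the package's own
test-design choices: probe grids of 15-89 windows, a 5-point lambda
sub-grid where the grid density is immaterial to the property under test,
and reduced resolution (16-32 channels, 128 Hz) for properties that do not
depend on spatial or temporal resolution (type-I calibration, STV-to-RT
cohort replicates, the group cluster comparison); peak-window and
forward-map recovery run at the full 64-channel/256 Hz defaults. Seeds are
fixed throughout; identical seeds reproduce identical results bit for bit.

Known limitations: the simulator's linear superposition cannot probe
robustness to artifacts or nonstationary noise; Az values near ceiling in
the default recovery regime compress the dynamic range of group
comparisons; the forward-model estimator carries an irreducible noise-
covariance tilt at finite SNR, so its correlation with the planted pattern
saturates slightly below 1 even at Az = 1.
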