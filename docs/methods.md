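# Methods

## What the package models

`vestikin` is a statistical pipeline for head-motion kinematics recorded with
inertial measurement units (IMUs) while subjects perform the ten standard
balance-stability exercises used in vestibular rehabilitation (tandem walks
and stances, quiet standing with eyes closed, standing on foam, foam-cup
tasks).  The motivating use case is unilateral vestibular loss (vestibular
schwannoma before and after surgical deafferentation, versus age-matched
controls): such subjects show larger trial-to-trial head-motion variability,
especially without visual input, and that variability tracks clinical scores
such as dynamic visual acuity (DVA), the Timed Up and Go (TUG), gait speed,
and the Functional Gait Assessment (FGA).

No public recordings exist for this paradigm, so the package ships a
first-class synthetic-data generator that reproduces the statistical
structure the analysis assumes, and every downstream stage is validated
against analytic oracles on that generator.

## Sway simulation

Each head channel (linear acceleration fore-aft/lateral/vertical in mG;
angular velocity roll/pitch/yaw in deg/s; 500 Hz, 30 s per trial) is an
independent stationary zero-mean Ornstein–Uhlenbeck process, discretized
exactly as an AR(1):

    x[k+1] = phi x[k] + sigma sqrt(1 - phi^2) eps[k],   phi = exp(-dt / tau)

with `x[0] ~ N(0, sigma^2)`.  The stationary SD `sigma` is the binding
contract (it is the quantity the analysis measures) and the autocorrelation
time `tau` (default 1 s) sets temporal smoothness.  Both admit closed forms
used directly in tests: the lag-1 autocorrelation is `exp(-dt/tau)`, and the
expectation of the mean-subtracted sample SD is

    E[s] ≈ sigma sqrt( N/(N-1) (1 - var(xbar)/sigma^2) ),
    var(xbar) = sigma^2/N^2 (N + 2 Σ_h (N-h) phi^h),

implemented as `expected_sample_sd`.  At 500 Hz, 30 s, tau = 1 s this sits
about 3.3 % below `sigma` — a property of any mean-subtracted SD estimator
under temporal correlation, not of this generator — so recovery tests
compare against `E[s]` rather than against `sigma` naively.

Default per-axis SDs come from the normative group × exercise table in
`reference_tables.py` (healthy control, preoperative, postoperative × the
ten exercises).  Axis independence is a deliberate simplification;
cross-axis covariance is an extension point, not a config flag.

Walking-type exercises use the same stationary-process contract at their
higher configured SDs; no gait-phase structure or inverted-pendulum
biomechanics is modeled, so passing tests say nothing about the spectral
shape of real walking data — only about variability-based measures.

## Near falls

Wrist/ankle sensors carry low-variance OU baselines.  Near-fall events are
Poisson-placed (default 0/trial for controls, 0.5/trial for VS groups),
non-overlapping, wholly inside the trial, and injected as half-sine pulses
on the three linear channels with amplitude 10× the channel's robust
baseline SD (`spike_sd_multiple`, chosen above the detection threshold so
injected events are detectable by construction).

The detector computes the vector magnitude of median-centered limb linear
acceleration, smooths it with a 50 ms boxcar, and thresholds the robust
z-score (median/MAD) at 6.  Smoothing matters: without it a white-noise
baseline crosses a 6-robust-SD threshold a fraction of a time per
15 000-sample trial, which would make the "quiet baseline → no events"
contract flaky.  Crossings closer than 0.5 s merge to the earliest
crossing.  All constants are config-exposed since no standard fixes them.

Each event excludes `[t, t + 0.3 s (support) + 2 s (recovery))` from the
in-balance time; the in-balance intervals are the complement, and
in-balance plus excluded time equals the trial duration identically.

## Kinematic measures

Per trial, over in-balance samples only: (i) duration in balance; (ii) the
mean of the three linear-axis SDs ("total acceleration SD"); (iii) per-axis
range of motion, `max |x - baseline|`; (iv) per-axis sample SD (n−1
denominator).  The stationary-state baseline is the per-axis mean over
in-balance samples (DC removal), which makes SD and ROM shift-invariant and
absorbs the static gravity component without tilt compensation; an
initial-window baseline is available via config.  No filtering is applied
by default (an optional 4-pole 20 Hz low-pass exists for real hardware).
The "sum all in-balance epochs" reading of duration is implemented;
first-epoch-only is a config choice left out deliberately (summing is what
the exclusion-window construction yields naturally).

## Composite kinematic score

Each measure is normalized per (exercise, measure) cell by the affine map
sending the reference mean to 50 and mean ± 2 SD to 0/100 (normalized mean
50, SD 25), signed so higher is always better (variability and ROM invert;
duration does not), then projected onto [0, 100].  The score is the equal-
weight mean over the selected exercise subset × measure grid, by default
the six per-axis SDs, over one of the subsets {foam eyes closed},
{+ tandem stance eyes closed}, {all three eyes-closed exercises}.  The
reference population is pooled across groups by default — the only choice
under which the normalized sample itself has mean 50 and SD 25 — with a
control-only mode for interpreting patient scores against the healthy
distribution.  Per-measure weights are accepted but default to equal, since
no principled weighting is established.

## Statistics

Two-sample comparisons use a pooled re-randomization test: `n_perm = 2000`
uniform rearrangements, two-sided by absolute difference of group means,
with the add-one estimator `p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)`
(strictly positive, valid under exchangeability; ties count as ≥, with a
1e-12 relative tolerance on the tie comparison).  Exhaustive enumeration is
available for small pools and is the oracle in tests; a sign-flip paired
variant supports pre-versus-post contrasts.  Pearson correlations use the
exact t-transform on n − 2 df.  No multiple-comparison correction is
applied anywhere by design; the correlation map reports raw p-values plus
two consistency criteria per measure pair: significance (p < 0.05) in the
majority of a category's exercises, and a common sign among all significant
cells (vacuously consistent when none is significant).

## Clinical co-generation

Each physical subject carries one latent impairment factor `z ~ N(0, 1)`
(shared between the pre- and postoperative time points of a VS subject).
The subject's sway SDs are the group/exercise cells scaled by the mean-one
log-normal multiplier `exp(lambda z - lambda^2/2)` (`kinematic_loading`
lambda, default 0.5, giving a between-subject coefficient of variation
≈ 0.53, of the order of the normative ± SD columns), and each clinical
measure is `intercept + loading z + N(0, noise_sd^2)` clipped to its range
(FGA 0–30, DHI/ABC 0–100, LogMAR −0.3–1.7, ...).  Because both sides are
affine in `z` on the log-SD scale, the population correlation has the
closed form

    rho = loading·lambda / sqrt( (loading² + noise²)(lambda² + v_e) ),

where `v_e = (1+phi²)/(2N(1-phi²))` is the variance that finite-trial SD
estimation adds to the log extracted SD.  `calibrate_noise_sd` inverts this
for `noise_sd` given a target correlation, which is how the generator is
pointed at the reference value r = 0.95 between lateral log-variability and
ipsilesional DVA; recovery is then measured on the *log* extracted SD.  The
single-factor construction makes all axes (and all loaded measures)
mutually correlated through `z` — adequate for correlation-recovery and
ordering checks, but real data have richer, measure-specific structure, and
the within-subject correlation across exercises implied by a shared latent
is an assumption, not an observation.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; cohort, trial, clinical,
and per-comparison seeds derive from a master seed by CRC32 hashing of
stage labels, so adding a stage never perturbs earlier streams, any
sub-cohort regenerates identical trials, and a rerun of `run_study`
reproduces every output file byte for byte.

Validation sizes: stationary-SD recovery and normative-cell recovery use 50
trials per cell (3-SE bands with empirical SEs); Monte-Carlo vs exhaustive
permutation agreement uses pooled sizes ≤ 10 and 2000 rearrangements; null
calibration uses 1000 replicates; correlation recovery uses a 500-subject
cohort; score boundedness uses 10 000 randomized subjects; the group-
ordering check uses 20 subjects per group over the three eyes-closed
exercises.  The default end-to-end study (9 per group × 10 exercises × 3
groups = 270 trials at 500 Hz) runs in well under a minute on one core.

## Known limitations

- No cross-axis or cross-exercise covariance beyond the single latent.
- Stationary Gaussian sway: no heavy tails, drift, or gait periodicity.
- The near-fall transient is a stylized half-sine; real compensatory
  movements are heterogeneous, so detector performance on real data must be
  re-tuned via the exposed thresholds.
- Clinical measures are linear-Gaussian-clipped fields; instrument-specific
  floor/ceiling behavior and test-retest noise are not modeled.
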