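"""Synthetic cohorts of balance-exercise IMU trials and clinical measures.

Head sway during a balance exercise is modeled per axis as a stationary
zero-mean Ornstein-Uhlenbeck (mean-reverting Gaussian) process with a
configurable stationary standard deviation and autocorrelation time.  The
exact AR(1) discretization is used, so the stationary SD and the lag-h
autocorrelation ``exp(-h*dt/tau)`` hold in closed form, which makes the
generator testable against analytic oracles.  Axes are generated
independently; walking exercises share the same stationary-process contract
at their (higher) configured SDs.

Wrist and ankle sensors carry low-variance baselines onto which occasional
near-fall transients (half-sine pulses on the linear channels, amplitude a
multiple of the baseline SD) are injected at Poisson-distributed times.

Clinical measures are co-generated with the kinematics through a single
per-subject latent impairment factor ``z ~ N(0, 1)``: each subject's sway
SDs are the group/exercise reference cells scaled by the mean-one log-normal
multiplier ``exp(lambda*z - lambda^2/2)``, and each clinical measure is
``intercept + loading*z + noise`` clipped to its admissible range.  The
population correlation between any clinical measure and log sway variability
therefore has the closed form used by :func:`implied_clinical_correlation`,
and loadings can be calibrated to hit a target correlation with
:func:`calibrate_noise_sd`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import InvalidParameterError
from .kinematics import IMURecording
from .reference_tables import AXES, GROUPS, SWAY_SD_MEAN
from .exercises import EXERCISES

#: quiescent wrist/ankle baseline SDs per channel (mG, mG, mG, dps, dps, dps)
LIMB_BASELINE_SD = (5.0, 5.0, 5.0, 0.5, 0.5, 0.5)

#: clinical measure column names
CLINICAL_MEASURES = (
    "dva_ipsi_logmar", "dva_contra_logmar", "tug_s", "gait_speed_mps",
    "fga", "vhit_gain_ipsi", "dhi", "abc", "hit6", "bai",
)


def derive_seed(master: int, *parts) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and a
    sequence of hashable labels, via CRC32 of their repr."""
    text = repr(("vestikin", int(master)) + tuple(parts))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class SwayModelParams:
    """Parameters of the per-axis stationary sway process for one trial.

    ``per_axis_sd`` holds the six stationary SD targets in axis order
    (fore-aft, lateral, vertical in mG; roll, pitch, yaw in deg/s).
    ``correlation_time_s`` is the exponential autocorrelation time of the
    sway (temporal smoothness), default 1 s.
    """

    per_axis_sd: tuple[float, ...]
    correlation_time_s: float = 1.0
    sample_rate_hz: float = 500.0
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        sd = tuple(float(s) for s in self.per_axis_sd)
        if len(sd) != 6 or any(s < 0 for s in sd):
            raise InvalidParameterError("per_axis_sd must be 6 nonnegative reals")
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("rate and duration must be positive")
        if self.correlation_time_s <= 0:
            raise InvalidParameterError("correlation_time_s must be positive")
        if self.correlation_time_s >= self.duration_s:
            raise InvalidParameterError(
                "correlation_time_s must be shorter than the trial"
            )
        n = self.sample_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-6:
            raise InvalidParameterError(
                "sample_rate_hz * duration_s must be an integer sample count"
            )
        object.__setattr__(self, "per_axis_sd", sd)

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.duration_s))

    @property
    def lag1_autocorrelation(self) -> float:
        """Closed-form lag-one autocorrelation of the discretized process."""
        return math.exp(-1.0 / (self.sample_rate_hz * self.correlation_time_s))


@dataclass(frozen=True)
class NearFallParams:
    """Near-fall transient injection parameters for wrist/ankle channels."""

    event_rate_per_trial: float = 0.0
    spike_sd_multiple: float = 10.0
    spike_duration_s: float = 0.3
    recovery_gap_s: float = 2.0

    def __post_init__(self) -> None:
        if self.event_rate_per_trial < 0 or self.recovery_gap_s < 0:
            raise InvalidParameterError("rates and gaps must be nonnegative")
        if self.spike_sd_multiple <= 0 or self.spike_duration_s <= 0:
            raise InvalidParameterError(
                "spike amplitude and duration must be positive"
            )


@dataclass(frozen=True)
class ClinicalGeneratorParams:
    """Latent-factor co-generation of clinical measures.

    Each measure is ``intercept + latent_loading*z + N(0, noise_sd^2)``
    clipped to ``bounds``; ``kinematic_loading`` is the loading of the same
    latent ``z`` onto the log sway-SD multiplier.  Loading signs encode
    directionality (positive = worse with impairment for DVA/TUG/DHI/HIT-6/
    BAI; negative for FGA, gait speed, ABC, and VOR gain).
    """

    latent_loading: Mapping[str, float]
    noise_sd: Mapping[str, float]
    intercept: Mapping[str, float]
    bounds: Mapping[str, tuple[float, float]]
    kinematic_loading: float = 0.5

    def __post_init__(self) -> None:
        for m, s in self.noise_sd.items():
            if s < 0:
                raise InvalidParameterError(f"noise_sd[{m!r}] must be >= 0")
        for m, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise InvalidParameterError(f"bounds[{m!r}] are degenerate")

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.latent_loading)


def default_clinical_params(kinematic_loading: float = 0.5) -> ClinicalGeneratorParams:
    """Default clinical generator: loadings sized so that impairment-linked
    measures (DVA, TUG, gait speed, FGA) correlate strongly with log sway
    variability while subjective scales correlate more weakly."""
    spec = {
        # measure: (intercept, loading, noise_sd, (lo, hi))
        "dva_ipsi_logmar": (0.35, 0.25, 0.08, (-0.3, 1.7)),
        "dva_contra_logmar": (0.25, 0.15, 0.10, (-0.3, 1.7)),
        "tug_s": (10.0, 2.0, 1.0, (2.0, 60.0)),
        "gait_speed_mps": (1.2, -0.15, 0.08, (0.1, 3.0)),
        "fga": (24.0, -4.0, 2.0, (0.0, 30.0)),
        "vhit_gain_ipsi": (0.8, -0.15, 0.08, (0.0, 1.5)),
        "dhi": (30.0, 15.0, 10.0, (0.0, 100.0)),
        "abc": (80.0, -10.0, 8.0, (0.0, 100.0)),
        "hit6": (44.0, 6.0, 8.0, (36.0, 78.0)),
        "bai": (10.0, 5.0, 6.0, (0.0, 63.0)),
    }
    return ClinicalGeneratorParams(
        latent_loading={m: v[1] for m, v in spec.items()},
        noise_sd={m: v[2] for m, v in spec.items()},
        intercept={m: v[0] for m, v in spec.items()},
        bounds={m: v[3] for m, v in spec.items()},
        kinematic_loading=kinematic_loading,
    )


def implied_clinical_correlation(
    loading: float,
    noise_sd: float,
    kinematic_loading: float,
    extraction_log_var: float = 0.0,
) -> float:
    """Closed-form population Pearson correlation between a clinical measure
    and log sway SD under the latent-factor model.

    Both variables are affine in the shared latent ``z`` plus independent
    Gaussian noise, so the correlation is the product of their attenuation
    factors.  ``extraction_log_var`` is the variance contributed to the log
    of the *extracted* SD by finite-trial estimation noise (see
    :func:`log_sd_estimator_variance`); leave it 0 for the correlation with
    the true per-subject log SD.
    """
    lam = kinematic_loading
    denom = math.sqrt(
        (loading * loading + noise_sd * noise_sd)
        * (lam * lam + extraction_log_var)
    )
    if denom == 0:
        raise InvalidParameterError("degenerate loadings: correlation undefined")
    return loading * lam / denom


def calibrate_noise_sd(
    target_r: float,
    loading: float,
    kinematic_loading: float,
    extraction_log_var: float = 0.0,
) -> float:
    """Solve for the clinical noise SD that makes the model-implied
    correlation (with the extracted log SD) equal ``target_r``.

    Raises if the target exceeds the attainable maximum given the kinematic
    loading and extraction noise.
    """
    lam2 = kinematic_loading * kinematic_loading
    rho2 = target_r * target_r
    if not 0 < abs(target_r) <= 1:
        raise InvalidParameterError("target_r must be in (0, 1]")
    if math.copysign(1.0, target_r) != math.copysign(1.0, loading * kinematic_loading):
        raise InvalidParameterError("target sign inconsistent with loading signs")
    ratio = lam2 / (rho2 * (lam2 + extraction_log_var))
    s2 = loading * loading * (ratio - 1.0)
    if s2 < 0:
        raise InvalidParameterError(
            f"target |r|={abs(target_r):.3f} unattainable: extraction noise "
            "caps the correlation below the target; raise kinematic_loading"
        )
    return math.sqrt(s2)


def log_sd_estimator_variance(params: SwayModelParams) -> float:
    """Approximate variance of log(sample SD) of one simulated channel.

    For a stationary Gaussian AR(1) with lag-one coefficient ``phi`` over
    ``N`` samples, ``var(hat_sigma^2) ~ (2 sigma^4 / N) sum_h rho(h)^2`` and
    the geometric sum gives ``var(log hat_sigma) ~ (1 + phi^2) /
    (2 N (1 - phi^2))``.
    """
    phi = params.lag1_autocorrelation
    n = params.n_samples
    return (1.0 + phi * phi) / (2.0 * n * (1.0 - phi * phi))


def expected_sample_sd(params: SwayModelParams, axis: int) -> float:
    """Closed-form expectation of the mean-subtracted sample SD (n-1
    denominator) of one generated channel.

    With temporally correlated samples the subtracted sample mean has
    non-negligible variance, so ``E[s^2] = (N/(N-1)) (sigma^2 - var(xbar))``
    sits a few percent below ``sigma^2``; the square root is returned
    (the Jensen correction at these sample sizes is < 1e-4 relative).
    """
    sigma = params.per_axis_sd[axis]
    if sigma == 0:
        return 0.0
    n = params.n_samples
    phi = params.lag1_autocorrelation
    h = np.arange(1, n)
    # var(xbar) = sigma^2/n^2 * (n + 2*sum_h (n-h) phi^h)
    var_mean = sigma**2 / n**2 * (n + 2.0 * np.sum((n - h) * phi**h))
    return math.sqrt(n / (n - 1) * (sigma**2 - var_mean))


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort.

    ``sway_params`` maps (group, exercise) to trial-level sway parameters and
    defaults to the normative reference table; ``near_fall_rate_by_group``
    sets the expected near-fall count per trial (controls rarely trigger
    events, so their default is 0).
    """

    n_per_group: int = 9
    groups: tuple[str, ...] = GROUPS
    exercises: tuple[int, ...] = tuple(EXERCISES)
    correlation_time_s: float = 1.0
    sample_rate_hz: float = 500.0
    duration_s: float = 30.0
    sway_params: Mapping[tuple[str, int], SwayModelParams] | None = None
    near_fall: NearFallParams = field(default_factory=NearFallParams)
    near_fall_rate_by_group: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 0.0, "preoperative": 0.5, "postoperative": 0.5,
        }
    )
    clinical: ClinicalGeneratorParams = field(
        default_factory=default_clinical_params
    )
    sensors: tuple[str, ...] = ("head", "left_wrist", "left_ankle")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be positive")
        if not self.groups or not self.exercises:
            raise InvalidParameterError("groups and exercises must be non-empty")
        for g in self.groups:
            if g not in GROUPS:
                raise InvalidParameterError(f"unknown group {g!r}")
        for e in self.exercises:
            if e not in EXERCISES:
                raise InvalidParameterError(f"unknown exercise id {e!r}")
        if "head" not in self.sensors:
            raise InvalidParameterError("sensors must include the head")
        for g in self.groups:
            for e in self.exercises:
                self.cell_params(g, e)  # raises if a cell is missing

    def cell_params(self, group: str, exercise: int) -> SwayModelParams:
        """Sway parameters for one (group, exercise) cell."""
        if self.sway_params is not None and (group, exercise) in self.sway_params:
            return self.sway_params[(group, exercise)]
        key = (group, exercise)
        if key not in SWAY_SD_MEAN:
            raise InvalidParameterError(f"no sway parameters for cell {key}")
        return SwayModelParams(
            per_axis_sd=SWAY_SD_MEAN[key],
            correlation_time_s=self.correlation_time_s,
            sample_rate_hz=self.sample_rate_hz,
            duration_s=self.duration_s,
        )

    def group_near_fall(self, group: str) -> NearFallParams:
        rate = self.near_fall_rate_by_group.get(group, 0.0)
        return replace(self.near_fall, event_rate_per_trial=rate)


@dataclass(frozen=True)
class Trial:
    """One simulated trial with its metadata and ground truth."""

    subject: str
    group: str
    exercise: int
    seed: int
    recordings: tuple[IMURecording, ...]
    true_axis_sd: tuple[float, ...]


@dataclass(frozen=True)
class Cohort:
    """A materialized synthetic cohort."""

    config: CohortConfig
    trials: tuple[Trial, ...]
    clinical: pd.DataFrame
    subjects: pd.DataFrame


def _ou_series(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Exact stationary AR(1) realization with stationary SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    w[0] *= sd
    w[1:] *= sd * math.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], w)


def add_transient(
    recording: IMURecording, start_s: float, duration_s: float, sd_multiple: float
) -> IMURecording:
    """Add one half-sine pulse to the three linear channels of a recording.

    The per-channel amplitude is ``sd_multiple`` times the channel's robust
    (MAD-based) baseline SD, so injected events are detectable by
    construction relative to that baseline.
    """
    fs = recording.sample_rate_hz
    i0 = int(round(start_s * fs))
    i1 = min(recording.n_samples, i0 + max(1, int(round(duration_s * fs))))
    if i0 < 0 or i0 >= recording.n_samples:
        raise InvalidParameterError("transient start outside the trial")
    ch = recording.channels.copy()
    t = np.arange(i1 - i0)
    pulse = np.sin(np.pi * (t + 0.5) / (i1 - i0))
    for c in range(3):
        x = ch[c]
        scale = 1.4826 * np.median(np.abs(x - np.median(x)))
        if scale == 0.0:
            scale = float(np.std(x)) or 1.0
        ch[c, i0:i1] = x[i0:i1] + sd_multiple * scale * pulse
    return IMURecording(recording.sensor_location, fs, ch)


def inject_near_falls(
    recording: IMURecording,
    near_fall: NearFallParams,
    seed: int,
) -> tuple[IMURecording, np.ndarray]:
    """Inject Poisson-placed near-fall transients into a limb recording.

    Returns the modified recording and the ground-truth event peak times.
    Events never overlap and lie wholly inside the trial window; with a zero
    event rate the recording is returned unchanged.
    """
    if not recording.is_limb:
        raise InvalidParameterError(
            "near-fall transients are injected on wrist/ankle sensors only"
        )
    dur = near_fall.spike_duration_s
    trial_s = recording.duration_s
    if dur >= trial_s:
        raise InvalidParameterError("spike_duration_s must be < trial duration")
    rng = np.random.default_rng(seed)
    count = int(rng.poisson(near_fall.event_rate_per_trial))
    if count == 0:
        return recording, np.empty(0)
    count = min(count, int(trial_s / (2 * dur)))  # physical capacity cap
    for _ in range(200):
        starts = np.sort(rng.uniform(0.0, trial_s - dur, size=count))
        if count == 1 or np.all(np.diff(starts) >= dur):
            break
    else:  # could not place this many disjoint events; thin them out
        starts = starts[np.r_[True, np.diff(starts) >= dur]]
    out = recording
    for s in starts:
        out = add_transient(out, s, dur, near_fall.spike_sd_multiple)
    return out, starts + dur / 2.0


def generate_trial(
    params: SwayModelParams,
    near_fall: NearFallParams | None = None,
    seed: int = 0,
    sensors: Sequence[str] = ("head", "left_wrist", "left_ankle"),
) -> list[IMURecording]:
    """Generate one trial's sensor recordings.

    The head sensor carries six independent stationary mean-reverting
    Gaussian channels at the configured per-axis SDs; wrist/ankle sensors
    carry low-variance baselines plus injected near-fall transients (if
    ``near_fall`` is given).  Identical seeds give identical samples.
    """
    rng = np.random.default_rng(seed)
    n = params.n_samples
    phi = params.lag1_autocorrelation
    out: list[IMURecording] = []
    for loc in sensors:
        sds = params.per_axis_sd if loc == "head" else LIMB_BASELINE_SD
        ch = np.vstack([_ou_series(rng, n, s, phi) for s in sds])
        rec = IMURecording(loc, params.sample_rate_hz, ch)
        if loc != "head" and near_fall is not None:
            rec, _ = inject_near_falls(
                rec, near_fall, seed=int(rng.integers(2**31))
            )
        out.append(rec)
    return out


def _subject_ids(config: CohortConfig) -> dict[str, list[str]]:
    """Physical subject ids per group; VS subjects are shared between the
    preoperative and postoperative groups."""
    ids: dict[str, list[str]] = {}
    for g in config.groups:
        prefix = "HC" if g == "control" else "VS"
        ids[g] = [f"{prefix}{i + 1:02d}" for i in range(config.n_per_group)]
    return ids


def _latent_factors(config: CohortConfig) -> dict[str, float]:
    """Latent impairment factor per physical subject (shared across the two
    VS time points)."""
    z: dict[str, float] = {}
    for g in config.groups:
        for s in _subject_ids(config)[g]:
            if s not in z:
                rng = np.random.default_rng(derive_seed(config.seed, "latent", s))
                z[s] = float(rng.standard_normal())
    return z


def generate_subject_table(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth subject table: latent factor and sway multiplier per
    (subject, group) row."""
    z = _latent_factors(config)
    lam = config.clinical.kinematic_loading
    rows = []
    for g in config.groups:
        for s in _subject_ids(config)[g]:
            mult = math.exp(lam * z[s] - lam * lam / 2.0)
            rows.append(
                {"subject": s, "group": g, "z": z[s], "sway_multiplier": mult}
            )
    return pd.DataFrame(rows)


def generate_clinical_table(config: CohortConfig) -> pd.DataFrame:
    """Clinical measures, one row per (subject, group/time point)."""
    cp = config.clinical
    z = _latent_factors(config)
    rows = []
    for g in config.groups:
        for s in _subject_ids(config)[g]:
            rng = np.random.default_rng(derive_seed(config.seed, "clinical", s, g))
            row: dict[str, object] = {"subject": s, "group": g}
            for m in cp.measures:
                val = (
                    cp.intercept[m]
                    + cp.latent_loading[m] * z[s]
                    + cp.noise_sd[m] * rng.standard_normal()
                )
                lo, hi = cp.bounds[m]
                row[m] = float(np.clip(val, lo, hi))
            rows.append(row)
    return pd.DataFrame(rows)


def iter_cohort_trials(config: CohortConfig) -> Iterator[Trial]:
    """Yield trials one at a time (memory-friendly for large cohorts).

    Trial seeds derive from the cohort seed and the (group, subject,
    exercise) labels, so any sub-cohort reproduces the identical trials.
    """
    subjects = generate_subject_table(config)
    mult = {
        (r.subject, r.group): r.sway_multiplier
        for r in subjects.itertuples()
    }
    for g in config.groups:
        nf = config.group_near_fall(g)
        for s in _subject_ids(config)[g]:
            for e in config.exercises:
                base = config.cell_params(g, e)
                sds = tuple(m * mult[(s, g)] for m in base.per_axis_sd)
                params = replace(base, per_axis_sd=sds)
                seed = derive_seed(config.seed, "trial", g, s, e)
                recs = generate_trial(params, nf, seed, config.sensors)
                yield Trial(
                    subject=s, group=g, exercise=e, seed=seed,
                    recordings=tuple(recs), true_axis_sd=sds,
                )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Materialize a full cohort: one trial per (subject, group, exercise),
    plus the clinical and ground-truth subject tables."""
    return Cohort(
        config=config,
        trials=tuple(iter_cohort_trials(config)),
        clinical=generate_clinical_table(config),
        subjects=generate_subject_table(config),
    )
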