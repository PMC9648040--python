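"""Kinematic feature extraction from 6-DOF inertial trial recordings.

A trial is a set of body-mounted IMU recordings (head plus optional wrist and
ankle sensors), each carrying three linear-acceleration channels (fore-aft,
lateral, vertical, in mG) and three angular-velocity channels (roll, pitch,
yaw, in deg/s) at a fixed sample rate (500 Hz by convention).

Four measure families are extracted per trial:

i.   ``duration_s`` — the in-balance time within the 30 s trial, i.e. the
     trial duration minus windows excluded around detected near-fall events;
ii.  ``total_accel_sd_mG`` — the per-axis SD of linear acceleration averaged
     over the three linear axes;
iii. ``rom`` — the range of motion: the maximum absolute deviation from the
     stationary baseline, per axis;
iv.  ``sd`` — the sample SD about the stationary baseline, per axis.

The "stationary state" baseline is the per-axis mean over in-balance samples
(DC removal), which makes SD and ROM invariant to constant channel offsets,
including the static gravity component on the linear channels.  Sample SDs
use the n-1 denominator.  Sample ``i`` covers the half-open time interval
``[i/rate, (i+1)/rate)`` and counts as in-balance iff ``i/rate`` falls inside
an in-balance interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .exceptions import (
    InvalidParameterError,
    MissingSensorError,
    UndefinedMeasureError,
)
from .reference_tables import AXES, LINEAR_AXES

SENSOR_LOCATIONS = (
    "head", "left_wrist", "right_wrist", "left_ankle", "right_ankle", "trunk",
)
LIMB_LOCATIONS = ("left_wrist", "right_wrist", "left_ankle", "right_ankle")

#: trial-file column names, in channel order
CHANNEL_NAMES = (
    "accel_foreaft_mG", "accel_lateral_mG", "accel_vertical_mG",
    "gyro_roll_dps", "gyro_pitch_dps", "gyro_yaw_dps",
)

#: per-axis measure column names used in measures tables
SD_COLUMNS = tuple(
    f"sd_{a}_mG" if a in LINEAR_AXES else f"sd_{a}_dps" for a in AXES
)
ROM_COLUMNS = tuple(
    f"rom_{a}_mG" if a in LINEAR_AXES else f"rom_{a}_dps" for a in AXES
)
MEASURE_COLUMNS = ("duration_s", "total_accel_sd_mG") + SD_COLUMNS + ROM_COLUMNS


@dataclass(frozen=True)
class IMURecording:
    """One sensor's 6-channel time series at a fixed sample rate.

    ``channels`` is a (6, n) float array in the order of
    :data:`CHANNEL_NAMES`: linear acceleration (mG) then angular velocity
    (deg/s).
    """

    sensor_location: str
    sample_rate_hz: float
    channels: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise InvalidParameterError(
                f"unknown sensor location: {self.sensor_location!r}"
            )
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be positive")
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[0] != 6:
            raise InvalidParameterError("channels must have shape (6, n)")
        if ch.shape[1] < 2:
            raise InvalidParameterError("recording needs at least 2 samples")
        if not np.all(np.isfinite(ch)):
            raise InvalidParameterError("recording contains non-finite values")
        object.__setattr__(self, "channels", ch)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]

    @property
    def is_limb(self) -> bool:
        return self.sensor_location in LIMB_LOCATIONS


@dataclass(frozen=True)
class BalanceSegmentation:
    """In-balance intervals of a trial and the near-fall events that cut it.

    Intervals are half-open ``[start_s, end_s)``, disjoint, sorted, and lie
    within ``[0, trial_duration_s]``.  ``excluded_time_s`` is defined as the
    complement, so in-balance plus excluded time equals the trial duration
    identically.
    """

    trial_duration_s: float
    in_balance_intervals: tuple[tuple[float, float], ...]
    near_fall_times: tuple[float, ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end in self.in_balance_intervals:
            if not (0.0 <= start < end <= self.trial_duration_s + 1e-12):
                raise InvalidParameterError(
                    f"interval [{start}, {end}) outside trial bounds"
                )
            if start < prev_end - 1e-12:
                raise InvalidParameterError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def in_balance_time_s(self) -> float:
        return float(sum(e - s for s, e in self.in_balance_intervals))

    @property
    def excluded_time_s(self) -> float:
        return self.trial_duration_s - self.in_balance_time_s

    def sample_mask(self, n_samples: int, sample_rate_hz: float) -> np.ndarray:
        """Boolean mask of samples whose start time lies in-balance."""
        mask = np.zeros(n_samples, dtype=bool)
        for start, end in self.in_balance_intervals:
            i0 = int(np.ceil(start * sample_rate_hz - 1e-9))
            i1 = int(np.ceil(end * sample_rate_hz - 1e-9))
            mask[max(i0, 0):min(i1, n_samples)] = True
        return mask


@dataclass(frozen=True)
class KinematicMeasures:
    """The four kinematic measure families for one trial.

    ``sd`` and ``rom`` are length-6 arrays in axis order (fore-aft, lateral,
    vertical, roll, pitch, yaw); linear entries are in mG, angular in deg/s.
    ``total_accel_sd_mG`` is identically the arithmetic mean of the three
    linear-axis SDs.  If the in-balance time is zero the variability measures
    are undefined and stored as NaN.
    """

    duration_s: float
    total_accel_sd_mG: float
    sd: np.ndarray
    rom: np.ndarray

    @property
    def defined(self) -> bool:
        return bool(np.all(np.isfinite(self.sd)) and np.all(np.isfinite(self.rom)))

    @classmethod
    def undefined(cls, duration_s: float = 0.0) -> "KinematicMeasures":
        nan6 = np.full(6, np.nan)
        return cls(duration_s, float("nan"), nan6, nan6.copy())

    def to_row(self) -> dict[str, float]:
        row = {
            "duration_s": self.duration_s,
            "total_accel_sd_mG": self.total_accel_sd_mG,
        }
        row.update(zip(SD_COLUMNS, self.sd))
        row.update(zip(ROM_COLUMNS, self.rom))
        return row


def detect_near_falls(
    limb_recordings: Sequence[IMURecording],
    threshold_sd_multiple: float = 6.0,
    min_event_separation_s: float = 0.5,
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Detect near-fall events from wrist/ankle acceleration transients.

    The detector forms the vector magnitude of limb linear acceleration after
    per-channel median removal, smooths it with a short boxcar, and reports
    an event wherever the smoothed magnitude exceeds its median by
    ``threshold_sd_multiple`` robust (MAD-based) standard deviations.  Events
    closer than ``min_event_separation_s`` are merged to the earliest
    threshold crossing.

    Returns the sorted event times (s); empty for quiescent input.
    """
    if threshold_sd_multiple <= 0:
        raise InvalidParameterError("threshold_sd_multiple must be positive")
    limbs = [r for r in limb_recordings if r.is_limb]
    if not limbs:
        raise MissingSensorError(
            "near-fall detection needs at least one wrist or ankle recording"
        )
    times: list[float] = []
    for rec in limbs:
        lin = rec.channels[:3]
        dev = lin - np.median(lin, axis=1, keepdims=True)
        mag = np.sqrt(np.sum(dev * dev, axis=0))
        k = max(1, int(round(smooth_s * rec.sample_rate_hz)))
        if k > 1:
            mag = np.convolve(mag, np.full(k, 1.0 / k), mode="same")
        med = np.median(mag)
        robust_sd = 1.4826 * np.median(np.abs(mag - med))
        if robust_sd == 0.0:
            continue  # flat signal: nothing to detect
        above = (mag - med) / robust_sd > threshold_sd_multiple
        starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        times.extend(starts / rec.sample_rate_hz)
    if not times:
        return np.empty(0)
    times_arr = np.sort(np.asarray(times))
    merged = [times_arr[0]]
    for t in times_arr[1:]:
        if t - merged[-1] >= min_event_separation_s:
            merged.append(t)
    return np.asarray(merged)


def segment_balance(
    duration_s: float,
    near_fall_times: Iterable[float],
    recovery_gap_s: float = 2.0,
    event_support_s: float = 0.3,
) -> BalanceSegmentation:
    """Split a trial into in-balance intervals around near-fall events.

    Each event at time ``t`` excludes the window
    ``[t, t + event_support_s + recovery_gap_s)`` (the transient's support
    plus the recovery period), clipped to the trial; overlapping exclusions
    are merged.  The in-balance intervals are the complement within
    ``[0, duration_s)``.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if recovery_gap_s < 0 or event_support_s < 0:
        raise InvalidParameterError("gap and support must be nonnegative")
    events = sorted(float(t) for t in near_fall_times)
    for t in events:
        if not (0.0 <= t <= duration_s):
            raise InvalidParameterError(
                f"event time {t} outside [0, {duration_s}]"
            )
    width = event_support_s + recovery_gap_s
    exclusions: list[tuple[float, float]] = []
    for t in events:
        lo, hi = t, min(duration_s, t + width)
        if exclusions and lo <= exclusions[-1][1]:
            exclusions[-1] = (exclusions[-1][0], max(exclusions[-1][1], hi))
        elif hi > lo:
            exclusions.append((lo, hi))
    intervals: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in exclusions:
        if lo > cursor:
            intervals.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration_s:
        intervals.append((cursor, duration_s))
    return BalanceSegmentation(
        trial_duration_s=duration_s,
        in_balance_intervals=tuple(intervals),
        near_fall_times=tuple(events),
    )


def _in_balance_samples(head: IMURecording, seg: BalanceSegmentation) -> np.ndarray:
    mask = seg.sample_mask(head.n_samples, head.sample_rate_hz)
    if mask.sum() < 2:
        raise UndefinedMeasureError(
            "fewer than 2 in-balance samples: variability measures undefined"
        )
    return mask


def _baseline(x: np.ndarray, mode: str, sample_rate_hz: float) -> float:
    if mode == "mean":
        return float(x.mean())
    if mode == "initial":
        n0 = max(2, min(len(x), int(round(sample_rate_hz))))
        return float(x[:n0].mean())
    raise InvalidParameterError(f"unknown baseline mode: {mode!r}")


def compute_sd_per_axis(
    head: IMURecording,
    seg: BalanceSegmentation,
    baseline: str = "mean",
) -> np.ndarray:
    """Per-axis sample SD (n-1 denominator) about the stationary baseline,
    over in-balance samples only."""
    mask = _in_balance_samples(head, seg)
    out = np.empty(6)
    for i in range(6):
        x = head.channels[i, mask]
        d = x - _baseline(x, baseline, head.sample_rate_hz)
        out[i] = np.sqrt(np.dot(d, d) / (len(d) - 1))
    return out


def compute_rom(
    head: IMURecording,
    seg: BalanceSegmentation,
    baseline: str = "mean",
) -> np.ndarray:
    """Per-axis range of motion: max absolute deviation from the stationary
    baseline over in-balance samples."""
    mask = _in_balance_samples(head, seg)
    out = np.empty(6)
    for i in range(6):
        x = head.channels[i, mask]
        out[i] = np.max(np.abs(x - _baseline(x, baseline, head.sample_rate_hz)))
    return out


def compute_total_accel_sd(sd: np.ndarray) -> float:
    """Arithmetic mean of the three linear-axis SDs."""
    sd = np.asarray(sd, dtype=float)
    if sd.shape != (6,):
        raise InvalidParameterError("expected 6 per-axis SDs")
    return float(sd[:3].mean())


def _lowpass(rec: IMURecording, cutoff_hz: float) -> IMURecording:
    sos = signal.butter(4, cutoff_hz, fs=rec.sample_rate_hz, output="sos")
    return IMURecording(
        rec.sensor_location, rec.sample_rate_hz,
        signal.sosfiltfilt(sos, rec.channels, axis=1),
    )


def extract_measures(
    recordings: Sequence[IMURecording],
    *,
    nf_threshold: float = 6.0,
    min_event_separation_s: float = 0.5,
    recovery_gap_s: float = 2.0,
    event_support_s: float = 0.3,
    baseline: str = "mean",
    lowpass_hz: float | None = None,
) -> KinematicMeasures:
    """Extract all four kinematic measure families from one trial.

    Uses the head sensor for the measures and any wrist/ankle sensors for
    near-fall detection; with no limb sensors the whole trial counts as
    in-balance.  Deterministic for fixed input.
    """
    heads = [r for r in recordings if r.sensor_location == "head"]
    if not heads:
        raise MissingSensorError("trial has no head recording")
    head = heads[0]
    limbs = [r for r in recordings if r.is_limb]
    if limbs:
        events = detect_near_falls(
            limbs, nf_threshold, min_event_separation_s
        )
    else:
        events = np.empty(0)
    seg = segment_balance(
        head.duration_s, events, recovery_gap_s, event_support_s
    )
    if lowpass_hz is not None:
        head = _lowpass(head, lowpass_hz)
    try:
        sd = compute_sd_per_axis(head, seg, baseline)
        rom = compute_rom(head, seg, baseline)
    except UndefinedMeasureError:
        return KinematicMeasures.undefined(seg.in_balance_time_s)
    return KinematicMeasures(
        duration_s=seg.in_balance_time_s,
        total_accel_sd_mG=compute_total_accel_sd(sd),
        sd=sd,
        rom=rom,
    )
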