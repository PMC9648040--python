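"""Delimited-text trial files and tables.

One CSV per sensor per trial (columns ``sample_index`` plus the six channel
columns), with a key-value sidecar (``<stem>.meta.txt``) carrying subject,
group, exercise id, sensor location, and sample rate.  Measures, clinical,
and score tables are plain CSVs handled by pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .kinematics import CHANNEL_NAMES, IMURecording
from .synthetic_data import Trial


def _trial_stem(subject: str, group: str, exercise: int, location: str) -> str:
    return f"{subject}_{group}_ex{exercise:02d}_{location}"


def write_trial(trial: Trial, out_dir: str | Path) -> list[Path]:
    """Write one trial's sensors as CSV + sidecar pairs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in trial.recordings:
        stem = _trial_stem(trial.subject, trial.group, trial.exercise,
                           rec.sensor_location)
        df = pd.DataFrame(rec.channels.T, columns=list(CHANNEL_NAMES))
        df.insert(0, "sample_index", np.arange(rec.n_samples))
        csv_path = out / f"{stem}.csv"
        df.to_csv(csv_path, index=False, float_format="%.6f")
        meta_path = out / f"{stem}.meta.txt"
        meta_path.write_text(
            f"subject: {trial.subject}\n"
            f"group: {trial.group}\n"
            f"exercise: {trial.exercise}\n"
            f"sensor_location: {rec.sensor_location}\n"
            f"sample_rate_hz: {rec.sample_rate_hz:g}\n"
        )
        paths += [csv_path, meta_path]
    return paths


def _parse_sidecar(path: Path) -> dict[str, str]:
    meta = {}
    for line in path.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_trials(
    trial_dir: str | Path,
) -> Iterator[tuple[dict[str, object], list[IMURecording]]]:
    """Iterate trials from a directory of CSV + sidecar pairs.

    Yields ``(meta, recordings)`` grouped by (subject, group, exercise);
    ``meta`` holds subject, group, and exercise (int).
    """
    trial_dir = Path(trial_dir)
    sidecars = sorted(trial_dir.glob("*.meta.txt"))
    if not sidecars:
        raise InvalidParameterError(f"no trial sidecars found in {trial_dir}")
    groups: dict[tuple[str, str, int], list[Path]] = {}
    for sc in sidecars:
        m = _parse_sidecar(sc)
        key = (m["subject"], m["group"], int(m["exercise"]))
        groups.setdefault(key, []).append(sc)
    for (subject, group, exercise), scs in sorted(groups.items()):
        recs = []
        for sc in sorted(scs):
            m = _parse_sidecar(sc)
            csv_path = sc.with_name(sc.name.replace(".meta.txt", ".csv"))
            df = pd.read_csv(csv_path)
            recs.append(IMURecording(
                sensor_location=m["sensor_location"],
                sample_rate_hz=float(m["sample_rate_hz"]),
                channels=df[list(CHANNEL_NAMES)].to_numpy().T,
            ))
        yield ({"subject": subject, "group": group, "exercise": exercise},
               recs)
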