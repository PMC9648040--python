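"""Normalization of kinematic measures and the 0-100 composite score.

Each raw measure ``x`` is normalized per (exercise, measure) cell against a
reference mean ``mu`` and SD ``sigma`` by the affine map that sends the
reference mean to 50 and ``mu +/- 2 sigma`` to the 0/100 endpoints
(normalized mean 50, normalized SD 25), with the sign chosen so that higher
normalized values are always better:

    raw = 50 - 25 (x - mu) / sigma    (higher raw value is worse)
    raw = 50 + 25 (x - mu) / sigma    (higher raw value is better)

Values outside [0, 100] are projected to the nearest endpoint.  The
composite kinematic score of a subject is the (optionally weighted) mean of
the normalized values over a selected exercise subset and measure set — by
default the six per-axis SDs — and runs from 0 (most altered) to 100
(comparable to healthy controls).

The reference population is pooled across all groups by default, the only
choice under which the sample of normalized values itself has mean 50 and
SD 25; a control-only reference is available for interpreting VS scores
against the healthy distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidParameterError,
    InvalidReferenceError,
    MissingDataError,
)
from .kinematics import MEASURE_COLUMNS, SD_COLUMNS

HIGHER_IS_WORSE = "higher_is_worse"
HIGHER_IS_BETTER = "higher_is_better"


def default_orientation(measure: str) -> str:
    """Duration is better when longer; every variability measure (SD, ROM,
    total-acceleration SD) is worse when larger."""
    return HIGHER_IS_BETTER if measure == "duration_s" else HIGHER_IS_WORSE


@dataclass(frozen=True)
class RefCell:
    mu: float
    sigma: float
    orientation: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidReferenceError("reference sigma must be positive")
        if self.orientation not in (HIGHER_IS_WORSE, HIGHER_IS_BETTER):
            raise InvalidReferenceError(
                f"unknown orientation {self.orientation!r}"
            )


@dataclass(frozen=True)
class NormalizationReference:
    """Reference mean/SD/orientation per (exercise, measure) cell."""

    cells: Mapping[tuple[int, str], RefCell]
    population: str = "pooled"

    def cell(self, exercise: int, measure: str) -> RefCell:
        try:
            return self.cells[(exercise, measure)]
        except KeyError:
            raise InvalidReferenceError(
                f"no reference cell for exercise {exercise}, measure {measure!r}"
            ) from None

    def to_json(self, path) -> None:
        payload = {
            "population": self.population,
            "cells": [
                {"exercise": e, "measure": m, "mu": c.mu, "sigma": c.sigma,
                 "orientation": c.orientation}
                for (e, m), c in sorted(self.cells.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationReference":
        with open(path) as fh:
            payload = json.load(fh)
        cells = {
            (int(c["exercise"]), c["measure"]): RefCell(
                c["mu"], c["sigma"], c["orientation"]
            )
            for c in payload["cells"]
        }
        return cls(cells=cells, population=payload.get("population", "pooled"))


@dataclass(frozen=True)
class KinematicScore:
    """A subject's composite score over an exercise subset, in [0, 100]."""

    subject: str
    exercise_subset: tuple[int, ...]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise InvalidParameterError("score must lie in [0, 100]")


def normalize_measure(
    x: float,
    mu: float,
    sigma: float,
    orientation: str = HIGHER_IS_WORSE,
    clip: bool = True,
) -> float:
    """Normalize one raw value against a reference cell.

    Returns ``50 +/- 25 (x - mu)/sigma`` (sign per orientation), projected
    onto [0, 100] unless ``clip`` is False.
    """
    if sigma <= 0:
        raise InvalidReferenceError("sigma must be positive")
    direction = -1.0 if orientation == HIGHER_IS_WORSE else 1.0
    raw = 50.0 + direction * 25.0 * (x - mu) / sigma
    if clip:
        return float(min(100.0, max(0.0, raw)))
    return float(raw)


def build_reference(
    measures: pd.DataFrame,
    exercises: Sequence[int] | None = None,
    measure_set: Sequence[str] | None = None,
    population: str = "pooled",
    group_col: str = "group",
    control_label: str = "control",
) -> NormalizationReference:
    """Estimate a normalization reference from a measures table.

    ``population`` is ``"pooled"`` (all rows) or ``"control_only"``.  Each
    cell needs at least two rows and nonzero spread; a degenerate cell
    raises naming the (exercise, measure).
    """
    if population == "control_only":
        measures = measures[measures[group_col] == control_label]
    elif population != "pooled":
        raise InvalidParameterError(f"unknown population {population!r}")
    if exercises is None:
        exercises = sorted(measures["exercise"].unique())
    if measure_set is None:
        measure_set = [c for c in MEASURE_COLUMNS if c in measures.columns]
    cells: dict[tuple[int, str], RefCell] = {}
    for e in exercises:
        sub = measures[measures["exercise"] == e]
        for m in measure_set:
            x = sub[m].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if len(x) < 2:
                raise InvalidReferenceError(
                    f"reference cell (exercise {e}, {m!r}) needs >= 2 subjects"
                )
            sigma = float(np.std(x, ddof=1))
            if sigma == 0.0:
                raise InvalidReferenceError(
                    f"reference cell (exercise {e}, {m!r}) has zero spread"
                )
            cells[(int(e), m)] = RefCell(
                float(np.mean(x)), sigma, default_orientation(m)
            )
    return NormalizationReference(cells=cells, population=population)


def kinematic_score(
    subject_measures: pd.DataFrame,
    reference: NormalizationReference,
    exercise_subset: Sequence[int],
    measure_set: Sequence[str] = SD_COLUMNS,
    weights: Mapping[str, float] | None = None,
    subject: str | None = None,
) -> KinematicScore:
    """Composite score for one subject: weighted mean of clipped normalized
    values over the selected (exercise x measure) grid.

    ``subject_measures`` holds that subject's per-trial rows (one per
    exercise).  A missing exercise raises :class:`MissingDataError` naming
    it; equal weights are used unless a per-measure weight map is given.
    """
    if subject is None:
        subject = str(subject_measures["subject"].iloc[0])
    vals: list[float] = []
    wts: list[float] = []
    for e in exercise_subset:
        rows = subject_measures[subject_measures["exercise"] == e]
        if rows.empty:
            raise MissingDataError(
                f"subject {subject}: no trial for exercise {e}"
            )
        row = rows.iloc[0]
        for m in measure_set:
            c = reference.cell(int(e), m)
            vals.append(normalize_measure(row[m], c.mu, c.sigma, c.orientation))
            wts.append(1.0 if weights is None else float(weights[m]))
    score = float(np.average(vals, weights=wts))
    return KinematicScore(
        subject=subject, exercise_subset=tuple(exercise_subset), score=score
    )


def score_cohort(
    measures: pd.DataFrame,
    reference: NormalizationReference,
    exercise_subset: Sequence[int],
    measure_set: Sequence[str] = SD_COLUMNS,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Score every (subject, group) in a measures table over one subset."""
    rows = []
    for (s, g), sub in measures.groupby(["subject", "group"], sort=True):
        ks = kinematic_score(
            sub, reference, exercise_subset, measure_set, weights, subject=s
        )
        rows.append({"subject": s, "group": g, "score": ks.score})
    return pd.DataFrame(rows)
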