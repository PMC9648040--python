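"""Permutation tests, Pearson correlations, and the correlation map.

Group comparisons use a two-sample re-randomization test: the two samples
are pooled, the pool is rearranged uniformly at random (2000 times by
default), and the observed difference of group means is compared with the
rearranged differences by absolute value (two-sided).  The Monte-Carlo
p-value uses the add-one estimator ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)``,
which is strictly positive and valid under the exchangeable null; exhaustive
enumeration over all splits is available for small pooled sizes, and a
sign-flip paired variant is provided for pre-versus-post contrasts.

Correlations between kinematic and clinical measures are Pearson
product-moment coefficients with two-sided p-values from the exact
t-transform on n - 2 degrees of freedom.  The correlation map evaluates
every (kinematic measure x clinical measure x exercise) cell within an
exercise category and summarizes each measure pair by two consistency
criteria: whether the correlation is significant (p < alpha) for the
majority of the category's exercises, and whether all significant
correlations share one sign.  No multiple-comparison correction is applied
anywhere; the map exposes raw p-values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

_MAX_EXHAUSTIVE = 500_000


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sample permutation test."""

    observed_diff: float
    n_perm: int
    p_two_sided: float
    seed: int | None
    n_a: int
    n_b: int
    method: str = "monte_carlo"
    paired: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CorrelationMap:
    """Per-cell correlations and per-pair consistency summaries.

    ``entries`` has one row per (kinematic, clinical, exercise) with r, p,
    n, significance, and sign; ``summary`` has one row per (kinematic,
    clinical) pair with ``n_significant``, ``majority_significant``,
    ``signs_consistent``, and the consistent sign (0 when mixed or none).
    """

    entries: pd.DataFrame
    summary: pd.DataFrame
    exercises: tuple[int, ...]
    alpha: float


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 2000,
    seed: int | None = None,
    method: str = "monte_carlo",
    paired: bool = False,
) -> PermutationResult:
    """Two-sided permutation test of the difference of group means.

    ``method`` is ``"monte_carlo"`` (default, ``n_perm`` random
    rearrangements, add-one p-value) or ``"exhaustive"`` (all splits of the
    pool, plain tie-inclusive proportion).  With ``paired=True`` the samples
    are paired by position and randomization flips the sign of each
    within-pair difference.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each group needs at least 2 values")
    if paired and x.size != y.size:
        raise InvalidParameterError("paired test needs equal-length groups")
    obs = float(x.mean() - y.mean())
    tol = 1e-12 * (1.0 + abs(obs))

    if paired:
        d = x - y
        if method == "exhaustive":
            if 2 ** d.size > _MAX_EXHAUSTIVE:
                raise InvalidParameterError("pool too large for exhaustive mode")
            signs = np.array(
                list(product([1.0, -1.0], repeat=d.size))
            )
            diffs = signs @ d / d.size
            count = int(np.sum(np.abs(diffs) >= abs(obs) - tol))
            p = count / len(diffs)
            return PermutationResult(obs, len(diffs), p, None,
                                     x.size, y.size, "exhaustive", True)
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        diffs = signs @ d / d.size
        count = int(np.sum(np.abs(diffs) >= abs(obs) - tol))
        p = (1 + count) / (n_perm + 1)
        return PermutationResult(obs, n_perm, p, seed,
                                 x.size, y.size, "monte_carlo", True)

    pooled = np.concatenate([x, y])
    n, na = pooled.size, x.size
    if method == "exhaustive":
        total = math.comb(n, na)
        if total > _MAX_EXHAUSTIVE:
            raise InvalidParameterError("pool too large for exhaustive mode")
        tot_sum = pooled.sum()
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            diff = sa / na - (tot_sum - sa) / (n - na)
            if abs(diff) >= abs(obs) - tol:
                count += 1
        return PermutationResult(obs, total, count / total, None,
                                 na, n - na, "exhaustive", False)
    if method != "monte_carlo":
        raise InvalidParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    mat = np.repeat(pooled[None, :], n_perm, axis=0)
    rng.permuted(mat, axis=1, out=mat)
    diffs = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
    count = int(np.sum(np.abs(diffs) >= abs(obs) - tol))
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(obs, n_perm, p, seed, na, n - na,
                             "monte_carlo", False)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided t-transform
    p-value on n - 2 degrees of freedom."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise InvalidParameterError("x and y must have equal length")
    if xa.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(float(res.statistic), float(res.pvalue), xa.size)


def build_correlation_map(
    kinematic: pd.DataFrame,
    clinical: pd.DataFrame,
    exercises: Sequence[int],
    kinematic_measures: Sequence[str] | None = None,
    clinical_measures: Sequence[str] | None = None,
    alpha: float = 0.05,
    subject_col: str = "subject",
) -> CorrelationMap:
    """Correlate every kinematic measure with every clinical measure for
    each exercise in a category, and summarize pair-level consistency.

    ``kinematic`` has one row per (subject, exercise) with measure columns;
    ``clinical`` one row per subject.  Cells whose correlation is undefined
    (zero variance) are recorded with NaN r and treated as non-significant.
    """
    from .kinematics import MEASURE_COLUMNS

    if kinematic_measures is None:
        kinematic_measures = [
            c for c in MEASURE_COLUMNS if c in kinematic.columns
        ]
    if clinical_measures is None:
        clinical_measures = [
            c for c in clinical.columns
            if c not in (subject_col, "group")
            and pd.api.types.is_numeric_dtype(clinical[c])
        ]
    entries = []
    for e in exercises:
        kdf = kinematic[kinematic["exercise"] == e]
        merged = kdf.merge(clinical, on=subject_col, suffixes=("", "_clin"))
        if len(merged) < 3:
            raise InsufficientDataError(
                f"exercise {e}: only {len(merged)} joined subjects (need >= 3)"
            )
        for km, cm in product(kinematic_measures, clinical_measures):
            pair = merged[[km, cm]].dropna()
            try:
                res = pearson(pair[km], pair[cm])
                r, p, n = res.r, res.p, res.n
            except (UndefinedCorrelationError, InvalidParameterError):
                r, p, n = float("nan"), float("nan"), len(pair)
            sig = bool(np.isfinite(p) and p < alpha)
            entries.append({
                "kinematic": km, "clinical": cm, "exercise": int(e),
                "r": r, "p": p, "n": n, "significant": sig,
                "sign": int(np.sign(r)) if np.isfinite(r) else 0,
            })
    entries_df = pd.DataFrame(entries)
    summary_rows = []
    n_ex = len(exercises)
    for (km, cm), sub in entries_df.groupby(["kinematic", "clinical"], sort=True):
        sig = sub[sub["significant"]]
        signs = set(sig["sign"])
        consistent = len(signs) <= 1
        summary_rows.append({
            "kinematic": km, "clinical": cm,
            "n_significant": int(len(sig)),
            "n_exercises": n_ex,
            "majority_significant": bool(len(sig) > n_ex / 2),
            "signs_consistent": consistent,
            "consistent_sign": signs.pop() if consistent and signs else 0,
        })
    return CorrelationMap(
        entries=entries_df,
        summary=pd.DataFrame(summary_rows),
        exercises=tuple(int(e) for e in exercises),
        alpha=alpha,
    )


def significance_stars(p: float) -> str:
    """Asterisk label for a p-value: *** < 0.001, ** < 0.01, * < 0.05."""
    if not 0.0 < p <= 1.0:
        raise InvalidParameterError("p must be in (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def flag_clinical_risk(clinical: Mapping[str, float]) -> dict[str, bool]:
    """Clinical fall-risk and vestibulo-ocular flags for one subject.

    Flags: ``tug_fall_risk`` when the Timed Up and Go exceeds 11.1 s;
    ``fga_fall_risk`` when the Functional Gait Assessment is strictly below
    22 of 30; and ``vhit_normal_<canal>`` when a video-head-impulse VOR gain
    lies within 0.8-1.2 with gain SD below 0.12 (requires matching
    ``vhit_gain_<canal>`` and ``vhit_gain_<canal>_sd`` fields).
    Out-of-range inputs (FGA outside 0-30, LogMAR outside -0.3..1.7,
    non-positive times/speeds) raise a validation error.
    """
    flags: dict[str, bool] = {}
    if "fga" in clinical:
        fga = float(clinical["fga"])
        if not 0.0 <= fga <= 30.0:
            raise ValidationError(f"FGA score {fga} outside 0-30")
        flags["fga_fall_risk"] = fga < 22.0
    if "tug_s" in clinical:
        tug = float(clinical["tug_s"])
        if tug <= 0.0:
            raise ValidationError("TUG time must be positive")
        flags["tug_fall_risk"] = tug > 11.1
    for key in clinical:
        if key.endswith("_logmar"):
            v = float(clinical[key])
            if not -0.3 <= v <= 1.7:
                raise ValidationError(f"{key}={v} outside LogMAR -0.3..1.7")
        if key.startswith("vhit_gain_") and not key.endswith("_sd"):
            sd_key = key + "_sd"
            if sd_key in clinical:
                gain = float(clinical[key])
                gain_sd = float(clinical[sd_key])
                if gain < 0 or gain_sd < 0:
                    raise ValidationError("vHIT gain and SD must be >= 0")
                canal = key[len("vhit_gain_"):]
                flags[f"vhit_normal_{canal}"] = (
                    0.8 <= gain <= 1.2 and gain_sd < 0.12
                )
    return flags
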