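"""End-to-end study pipeline: simulate, extract, score, compare, correlate.

:func:`run_study` reproduces the study's full result surface on a synthetic
cohort: a group summary of the six per-axis SDs per exercise, a significance
grid of permutation tests for every group pair over all 14 kinematic
measures per exercise, correlation maps between preoperative kinematic and
clinical measures for each exercise category, and composite kinematic-score
distributions for the standard exercise subsets.  All randomness derives
from one master seed by stable hashing of stage names, so re-running a
config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import InsufficientDataError, InvalidParameterError
from .exercises import (
    CATEGORY_MEMBERS,
    SCORE_SUBSETS,
    classify_exercise,  # noqa: F401  (re-exported pipeline surface)
)
from .kinematics import MEASURE_COLUMNS, SD_COLUMNS, extract_measures
from .scoring import NormalizationReference, build_reference, score_cohort
from .stats import (
    CorrelationMap,
    build_correlation_map,
    permutation_test,
    significance_stars,
)
from .synthetic_data import (
    CohortConfig,
    derive_seed,
    generate_clinical_table,
    generate_subject_table,
    iter_cohort_trials,
)

log = logging.getLogger("vestikin")

GROUP_PAIRS = (
    ("control", "preoperative"),
    ("control", "postoperative"),
    ("preoperative", "postoperative"),
)


@dataclass(frozen=True)
class ExtractionParams:
    nf_threshold: float = 6.0
    min_event_separation_s: float = 0.5
    recovery_gap_s: float = 2.0
    event_support_s: float = 0.3
    baseline: str = "mean"
    lowpass_hz: float | None = None


@dataclass(frozen=True)
class ScoringParams:
    reference_population: str = "pooled"
    subsets: tuple[str, ...] = tuple(SCORE_SUBSETS)
    measure_set: tuple[str, ...] = SD_COLUMNS


@dataclass(frozen=True)
class StatsParams:
    n_perm: int = 2000
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Master configuration of a study run; one master seed derives every
    stage seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        def build(klass, section):
            return klass(**section) if section else klass()

        cohort_d = dict(d.get("cohort", {}))
        for key in ("groups", "exercises", "sensors"):
            if key in cohort_d:
                cohort_d[key] = tuple(cohort_d[key])
        return cls(
            cohort=CohortConfig(**cohort_d),
            extraction=build(ExtractionParams, d.get("extraction")),
            scoring=build(ScoringParams, d.get("scoring")),
            stats=build(StatsParams, d.get("stats")),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class StudyReport:
    """All result tables of one study run."""

    config: RunConfig
    measures: pd.DataFrame
    clinical: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    reference: NormalizationReference
    scores: pd.DataFrame
    score_comparisons: pd.DataFrame
    correlation_maps: dict[str, CorrelationMap]
    stage_seeds: dict[str, int]


def simulate_measures(
    cohort: CohortConfig,
    extraction: ExtractionParams = ExtractionParams(),
) -> pd.DataFrame:
    """Generate a cohort trial by trial and extract its kinematic measures.

    Streams trials (recordings are discarded after extraction), returning
    one row per (subject, group, exercise) with the 14 measure columns plus
    the number of detected near falls.
    """
    rows = []
    for trial in iter_cohort_trials(cohort):
        km = extract_measures(
            trial.recordings,
            nf_threshold=extraction.nf_threshold,
            min_event_separation_s=extraction.min_event_separation_s,
            recovery_gap_s=extraction.recovery_gap_s,
            event_support_s=extraction.event_support_s,
            baseline=extraction.baseline,
            lowpass_hz=extraction.lowpass_hz,
        )
        row: dict[str, object] = {
            "subject": trial.subject,
            "group": trial.group,
            "exercise": trial.exercise,
        }
        row.update(km.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_groups(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the six per-axis SD measures per (group, exercise)."""
    rows = []
    for (g, e), sub in measures.groupby(["group", "exercise"], sort=True):
        row: dict[str, object] = {"group": g, "exercise": e, "n": len(sub)}
        for c in SD_COLUMNS:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    measures: pd.DataFrame,
    group_a: str,
    group_b: str,
    n_perm: int = 2000,
    seed: int = 0,
    measure_set: Sequence[str] = MEASURE_COLUMNS,
) -> pd.DataFrame:
    """Permutation-test grid over (exercise x measure) for one group pair.

    Each cell's seed derives from the stage seed and the cell labels, so the
    grid is reproducible and independent of evaluation order.
    """
    rows = []
    for e in sorted(measures["exercise"].unique()):
        sub = measures[measures["exercise"] == e]
        a = sub[sub["group"] == group_a]
        b = sub[sub["group"] == group_b]
        if len(a) < 2 or len(b) < 2:
            raise InvalidParameterError(
                f"exercise {e}: groups {group_a}/{group_b} need >= 2 subjects"
            )
        for m in measure_set:
            av = a[m].dropna().to_numpy()
            bv = b[m].dropna().to_numpy()
            res = permutation_test(
                av, bv, n_perm=n_perm,
                seed=derive_seed(seed, "compare", group_a, group_b, int(e), m),
            )
            log.info(
                "compare %s vs %s ex%d %s: diff=%.4g p=%.4g (n_perm=%d seed=%d)",
                group_a, group_b, e, m, res.observed_diff, res.p_two_sided,
                res.n_perm, res.seed,
            )
            rows.append({
                "group_a": group_a, "group_b": group_b, "exercise": int(e),
                "measure": m,
                "mean_a": float(av.mean()), "mean_b": float(bv.mean()),
                "observed_diff": res.observed_diff,
                "p": res.p_two_sided,
                "stars": significance_stars(res.p_two_sided),
                "seed": res.seed, "n_perm": res.n_perm,
            })
    return pd.DataFrame(rows)


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full pipeline and (optionally) write all outputs.

    Stages: simulate the cohort and extract measures; summarize groups;
    permutation-compare every group pair per (exercise, measure); build the
    normalization reference and score each exercise subset; permutation-
    compare scores between groups; and build per-category correlation maps
    for the preoperative cohort.
    """
    stage_seeds = {
        s: derive_seed(config.seed, s)
        for s in ("simulate", "stats", "scores")
    }
    cohort = dataclasses.replace(config.cohort, seed=stage_seeds["simulate"])
    measures = simulate_measures(cohort, config.extraction)
    clinical = generate_clinical_table(cohort)
    subjects = generate_subject_table(cohort)

    group_summary = summarize_groups(measures)

    comp_frames = []
    for ga, gb in GROUP_PAIRS:
        if ga in cohort.groups and gb in cohort.groups:
            comp_frames.append(compare_groups(
                measures, ga, gb,
                n_perm=config.stats.n_perm, seed=stage_seeds["stats"],
            ))
    comparisons = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames else pd.DataFrame()
    )

    reference = build_reference(
        measures,
        measure_set=list(config.scoring.measure_set),
        population=config.scoring.reference_population,
    )
    score_frames = []
    score_comp_rows = []
    for name in config.scoring.subsets:
        subset = SCORE_SUBSETS[name]
        if not set(subset) <= set(cohort.exercises):
            continue
        sdf = score_cohort(measures, reference, subset,
                           config.scoring.measure_set)
        sdf.insert(2, "subset", name)
        score_frames.append(sdf)
        for ga, gb in GROUP_PAIRS:
            if ga in cohort.groups and gb in cohort.groups:
                a = sdf[sdf["group"] == ga]["score"].to_numpy()
                b = sdf[sdf["group"] == gb]["score"].to_numpy()
                res = permutation_test(
                    a, b, n_perm=config.stats.n_perm,
                    seed=derive_seed(stage_seeds["scores"], name, ga, gb),
                )
                score_comp_rows.append({
                    "subset": name, "group_a": ga, "group_b": gb,
                    "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                    "observed_diff": res.observed_diff, "p": res.p_two_sided,
                    "stars": significance_stars(res.p_two_sided),
                    "seed": res.seed,
                })
    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames else pd.DataFrame()
    )
    score_comparisons = pd.DataFrame(score_comp_rows)

    correlation_maps: dict[str, CorrelationMap] = {}
    if "preoperative" in cohort.groups:
        pre_kin = measures[measures["group"] == "preoperative"]
        pre_clin = clinical[clinical["group"] == "preoperative"]
        for cat, members in CATEGORY_MEMBERS.items():
            ex = sorted(members & set(cohort.exercises))
            if not ex:
                continue
            try:
                correlation_maps[cat] = build_correlation_map(
                    pre_kin, pre_clin.drop(columns=["group"]), ex,
                    alpha=config.stats.alpha,
                )
            except InsufficientDataError as err:
                log.warning("correlation map %s skipped: %s", cat, err)

    report = StudyReport(
        config=config, measures=measures, clinical=clinical,
        group_summary=group_summary, comparisons=comparisons,
        reference=reference, scores=scores,
        score_comparisons=score_comparisons,
        correlation_maps=correlation_maps, stage_seeds=stage_seeds,
    )
    if out_dir is not None:
        write_report(report, out_dir, subjects=subjects)
    return report


def write_report(
    report: StudyReport,
    out_dir: str | Path,
    subjects: pd.DataFrame | None = None,
) -> None:
    """Write every report table as CSV plus a JSON index of seeds/counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "measures.csv": report.measures,
        "clinical.csv": report.clinical,
        "group_summary.csv": report.group_summary,
        "comparisons.csv": report.comparisons,
        "scores.csv": report.scores,
        "score_comparisons.csv": report.score_comparisons,
    }
    if subjects is not None:
        tables["subjects.csv"] = subjects
    for cat, cmap in report.correlation_maps.items():
        tables[f"correlation_entries_{cat}.csv"] = cmap.entries
        tables[f"correlation_summary_{cat}.csv"] = cmap.summary
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.12g")
    report.reference.to_json(out / "reference.json")
    index = {
        "seed": report.config.seed,
        "stage_seeds": report.stage_seeds,
        "n_trials": int(len(report.measures)),
        "groups": list(report.config.cohort.groups),
        "exercises": [int(e) for e in report.config.cohort.exercises],
        "files": sorted(tables) + ["reference.json"],
    }
    (out / "report.json").write_text(json.dumps(index, indent=1, sort_keys=True))


def plot_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Optional summary plots (score distributions per subset); requires
    matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, sub in report.scores.groupby("subset"):
        fig, ax = plt.subplots(figsize=(5, 3))
        for g, gsub in sub.groupby("group"):
            ax.hist(gsub["score"], bins=np.linspace(0, 100, 21),
                    alpha=0.5, label=g)
        ax.set_xlabel("kinematic score")
        ax.set_ylabel("subjects")
        ax.set_title(name)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / f"scores_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
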