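# vestikin

Quantitative analysis of **head-motion kinematics during balance-stability
exercises**, built for researchers and rehabilitation engineers studying
vestibular loss with body-worn inertial measurement units (IMUs).

Subjects with unilateral vestibular hypofunction (e.g. vestibular
schwannoma, before and after surgical deafferentation) sway more than
healthy controls while holding challenging stances — tandem stance,
standing on foam, eyes closed — and the variability of their head motion
tracks clinical scores such as dynamic visual acuity (DVA), the Timed Up
and Go (TUG), and the Functional Gait Assessment (FGA).  `vestikin` turns
that analysis into a tested, reusable pipeline:

- **synthetic_data** — cohorts of 6-DOF head/wrist/ankle trial recordings
  (stationary Ornstein–Uhlenbeck sway at normative per-axis SDs, Poisson
  near-fall transients) with clinical measures co-generated through a
  per-subject latent impairment factor;
- **kinematics** — near-fall detection, balance segmentation, and the four
  trial-level measure families: in-balance duration, per-axis SD σᵢ and
  range of motion ROMᵢ (i ∈ {fore-aft, lateral, vertical, roll, pitch,
  yaw}), and total acceleration SD = mean of the three linear σᵢ;
- **scoring** — per-cell normalization `50 ± 25·(x − μ)/σ` (reference mean
  → 50, mean ± 2 SD → 0/100, projected to [0, 100]) and the composite
  0–100 kinematic score, the mean over a chosen exercise subset × the six
  per-axis SDs;
- **stats** — pooled two-sample re-randomization tests (2000
  rearrangements, add-one two-sided p), Pearson correlation maps with
  majority-significance and sign-consistency summaries, and clinical risk
  flags (TUG > 11.1 s, FGA < 22, VOR gain 0.8–1.2 with SD < 0.12);
- **pipeline** — one-seed, byte-reproducible orchestration of
  simulate → extract → score → compare → correlate.

## Worked example

```python
from vestikin.pipeline import RunConfig, run_study
from vestikin.synthetic_data import CohortConfig

cfg = RunConfig(cohort=CohortConfig(n_per_group=9, exercises=(5, 6, 7)), seed=1)
rep = run_study(cfg)   # pass out_dir=... to also write all CSV/JSON tables
print(rep.group_summary[["group", "exercise", "sd_foreaft_mG_mean"]])
print(rep.score_comparisons.query("subset == 'eyes-closed-3'"))
```

prints (abridged) the fore-aft sway SD per group and the kinematic-score
comparison over the three eyes-closed exercises:

```
        group  exercise  sd_foreaft_mG_mean
      control         6                21.0
 preoperative         6                54.4
postoperative         6                51.2

       subset      group_a       group_b  mean_a  mean_b     p stars
eyes-closed-3      control  preoperative  69.652  41.841 0.002    **
eyes-closed-3      control postoperative  69.652  40.367 0.001    **
eyes-closed-3 preoperative postoperative  41.841  40.367 0.886
```

Controls sway least (fore-aft SD ≈ 21 mG vs ≈ 51–54 mG in the patient
groups while standing eyes-closed) and score closest to 100; both patient
groups score significantly lower, with little pre-versus-post difference —
the qualitative pattern the pipeline is designed to quantify.

The same stages are available from the shell:

```sh
vestikin simulate --config run.yaml --out sim/ --seed 1
vestikin extract  --in sim/trials --out measures.csv
vestikin score    --measures measures.csv --subset eyes-closed-3 --out scores.csv
vestikin report   --config run.yaml --out report/ --seed 1
```

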