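# effortpain

Simulation, hierarchical Bayesian modelling and model comparison for a
pain-avoidance prosocial effort task.

On each trial of the task a participant chooses between a **rest offer**
(6 electric shocks, no effort) and a **work offer** (1–5 shocks for gripping
at 40–80% of maximum voluntary contraction), in half of the trials for
themselves and in half for another person. This package provides the full
computational pipeline around that design:

- **`task_design`** — pseudo-randomized trial schedules (mini-blocks of the
  five effort levels, recipient runs ≤ 4, balanced effort × shock cells per
  recipient) with a constraint validator and CSV round-trip.
- **`value_models`** — the three effort-discounting subjective-value shapes
  (linear, parabolic, hyperbolic), the two-option softmax choice rule, and
  the 12-model catalog (shape × shared/separate κ × shared/separate β) with
  self/other effect coding (κ_other = κ_self + κ_effect).
- **`synthetic_data`** — agent populations and full synthetic datasets
  (choices, RTs, force AUC, success flags, non-responses, delivered-shock
  contingencies) with a grid-exact β calibration against target work-choice
  rates.
- **`inference`** — hierarchical Bayesian fitting of any of the 12 models
  with a self-contained NUTS sampler (analytic gradients, Stan-style warmup,
  diagonal mass adaptation), Normal(0,1) group priors, smooth negativity
  links for κ, rank-normalized split R-hat, shortest-interval HDIs, the
  R-hat > 1.05 subject-exclusion rule, and text-based fit serialization.
- **`model_comparison`** — PSIS-LOO (Pareto-smoothed importance sampling
  with the Zhang–Stephens tail fit) implemented from scratch, group and
  per-subject LOOIC, best-model attribution with parsimony tie-breaking.
- **`validation`** — posterior predictive checks (cell-wise choice rates
  with predictive bands) and the parameter-recovery study (group
  truth-in-HDI checks, subject-level true-vs-recovered correlations).
- **`behavioral_stats`** — per-subject/recipient behavioral summaries and
  default-prior Bayes factors: the JZS paired t-test BF (Cauchy prior,
  r scale 0.707) and the default-prior Pearson correlation BF, both by
  direct numerical integration (validated against independent quadrature
  oracles and pingouin to machine precision).
- **`pipeline` / `cli`** — YAML-configured end-to-end orchestration with
  fully logged sub-seeds and a JSON manifest.

## Command line

```bash
effortpain schedule --n 75 --seed 1 --out schedule.csv
effortpain simulate --config pop.yaml --schedule schedule.csv \
    --out data.csv --truth truth.csv
effortpain fit --data data.csv --model parabolic_2k1b \
    --chains 4 --warmup 1000 --samples 1000 --seed 11 --out fit_dir/
effortpain compare fit_dir1 fit_dir2 --out comparison.json
effortpain validate --fit fit_dir --mode ppc --seed 3 --out ppc.csv
effortpain stats --data data.csv --out stats.json
effortpain run --config run.yaml --out run_dir/
```

A minimal `run.yaml`:

```yaml
seed: 17
n_per_recipient: 75
population: {n_subjects: 47}
models: [parabolic_2k1b, parabolic_2k2b]
sampler: {n_chains: 4, n_warmup: 1000, n_samples: 1000}
```

## Dataset CSV schema

One row per trial per subject, comma-delimited UTF-8:

| column | values |
| --- | --- |
| `subject_id` | any identifier |
| `trial` | 1-based trial index |
| `recipient` | `self` / `other` |
| `effort_level` | 1–5 (40–80% MVC) |
| `work_shocks` | 1–5 |
| `choice` | `work` / `rest` / `nonresponse` |
| `rt_s` | choice RT in (0, 4) s; empty for non-responses |
| `force_auc` | fraction of MVC in (0, 1]; work trials only |
| `success` | `True`/`False`; work trials only |
| `delivered_shocks` | `work_shocks` if successful work, 6 after rest, 10 after failure/non-response |

`effortpain.io.read_dataset` validates all of this with row-indexed errors.
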