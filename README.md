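# sportfs

Feature-level evaluation of exercise effects from tabular physical-fitness
data. Given a cohort of participants described by numeric indicators
(height, resting heart rate, sprint times, …) and a binary label
(competition vs. non-competition participation), `sportfs` ranks the
indicators by how strongly participation influences them and quantifies how
well the ranking and the induced classifier perform. It is aimed at sports-
science and health-informatics analysts who need an interpretable,
reproducible alternative to black-box mining of fitness records.

## What is inside

* **A weighted random forest.** Trees grown on bootstrap resamples select
  splits by base-2 information gain, `g(X,A) = Ent(X) − Ent(X|A)` with
  `Ent(X) = −Σ pᵢ log₂ pᵢ`, over random feature subsets. Each tree votes
  with a weight proportional to its out-of-bag accuracy, normalized to sum
  to one. Indicator importance is the normalized per-feature sum of Gini
  decreases (`Gini_m = 1 − Σ p²_mk`) across all splits and trees; a
  noise-perturbation (OOB permutation) importance and iterative
  lowest-fraction feature elimination are included.
* **An opposition-based-learning artificial raindrop optimizer (OBL+ARA).**
  A population metaheuristic whose candidates flow toward a fixed-capacity
  elite pool, with the bound-reflected inverse point `c'ᵢ = bᵢ + dᵢ − cᵢ`
  evaluated for every new candidate and kept when fitter, an adaptive flow
  coefficient `β_{t+1} = β_t(1 − t/T)`, and stagnation escapes. Used to tune
  forest hyperparameters; benchmarked against plain ARA, differential
  evolution and inertia-weight PSO on the Ackley and Rastrigin functions.
* **An evaluation pipeline.** Mean imputation, 3σ outlier-row removal,
  stratified 70/30 split, grid search over tree count × depth with
  stratified 5-fold CV, accuracy/precision/recall/F1, and top@k precision
  of the importance ranking against ground truth (the fraction of the k
  best-ranked indicators that are truly influential).
* **A synthetic cohort generator** that plants a known set of informative
  indicators with configurable effect sizes, plus missing cells and >3σ
  outliers, so every stage is testable end to end with an exact ground
  truth. See `docs/methods.md` for what the generator does and does not
  emulate.

## Worked example

```bash
sportfs --quiet simulate --out cohort.csv --seed 3 --n-participants 300 \
        --missing-rate 0.01 --outlier-rate 0.005
sportfs --quiet preprocess --data cohort.csv --out clean.csv
sportfs --quiet evaluate --data clean.csv --seed 0 --n-trees 50
```

prints (abridged):

```
imputed 60 cells, removed 35 rows -> clean.csv
Feature ranking (normalized importance):
    1  balance_one_leg_s        0.2362
    2  sprint_50m_s             0.2063
    3  run_800m_s               0.1227
    4  body_fat_pct             0.1119
    5  vital_capacity_ml        0.0815
    6  sit_and_reach_cm         0.0276
  ...
Held-out metrics (positive = competition): accuracy 0.962, precision 0.971, recall 0.944, F1 0.958
Ground-truth recovery: top@3 1.00, top@5 1.00, top@10 0.50
```

The cohort was generated with five planted informative indicators
(`balance_one_leg_s`, `sprint_50m_s`, `run_800m_s`, `body_fat_pct`,
`vital_capacity_ml`); after repairing the injected corruption (60 blanked
cells imputed, 35 rows with >3σ cells removed), the forest's importance
ranking recovers exactly those five in the top five positions
(top@3 = top@5 = 1.00) and the weighted vote classifies the held-out 30%
with 96% accuracy. `top@10 0.50` simply reflects that only 5 of 10
possible hits exist.

The same flow is available as library calls
(`generate_dataset`, `preprocess`, `split`, `grid_search`,
`WeightedRandomForestClassifier`, `effect_report`), and the forest is a
scikit-learn-compatible estimator usable inside sklearn model selection.
The optimizer benchmark is `sportfs benchmark --function ackley --dim 10
--budget 1000 --runs 30 --seed 0`.

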