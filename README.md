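# fdqp — federated data-quality profiling for edge-held patient data

Continuous patient monitoring scatters data across edge nodes that cannot
ship their raw tables to a server: sensors drift, transmissions drop cells,
and a single degraded node can silently poison any model trained on the
federation.  `fdqp` implements **federated data-quality profiling**: instead
of data, the nodes exchange small versioned *data-quality profiles* (DQPs),
and the server turns them into binding repair rules, node-selection
decisions and a cross-node feature ranking.  The target audience is health
informatics / biostatistics practitioners simulating or orchestrating
quality assurance for multi-site tabular patient data.

## The model

A profile is the tuple **(A, W, D, T, R, M)**: attributes *A* with
importance weights *W* (Σw = 1), quality dimensions *D* ⊆ {completeness,
accuracy, timeliness, uniqueness, validity, consistency}, minimum tolerance
levels *T*, repair rules *R*, and measured statistics *M* (min, max, mode,
skewness, missing/unique/outlier fractions, coefficient of variation).
Profiles are serialized to a schema-validated XML dialect and, after the
first federation round, only field-level deltas are exchanged.

Dimension metrics are the standard closed forms

    completeness = 1 − missing/total
    timeliness   = max(1 − currency/volatility, 0)^s
    correctness  = 1/(d(w, w_m) + 1)
    consistency  = 1/(1 + CV),   CV = sd/|mean|

Each federation round runs: **broadcast → edge profiling → node selection
(eliminate nodes whose measured dimensions fall below tolerance) → group
aggregation (min of minima, max of maxima, row-count-weighted means) →
federated feature selection → rule application → patient-similarity
evaluation**, incrementing the profile version until the federated accuracy
reaches the target `q_tol` or `max_rounds` is hit.

Missing-data rules map a column's missing fraction mf, skew and
missingness mechanism to an action: mean imputation (symmetric, mf < 20%),
median (skewed), mode (categorical), KNN (systematically missing / MNAR),
pooled stochastic-regression multiple imputation (20% ≤ mf < 50%, with
m = max(5, round(100·mf)) draws) and column deletion (mf ≥ 50%).

Feature selection is rank aggregation: per-node feature value (ANOVA F
against the class label), outlier % and missing % are summed across nodes,
each criterion is ranked (1 = best), and the **federated rank** is the exact
sum of the three ranks — the lowest-sum features are kept.

The accuracy signal is a deliberately simple patient-similarity network:
a Gaussian kernel on z-scored features with leave-one-out
most-similar-patient classification, federated as a row-count-weighted
mean of per-edge accuracies.

## Worked example

```python
import logging; logging.disable(logging.WARNING)
from fdqp import (standard_corrupted_scenario, make_baseline_profile,
                  run_federation, compare_pre_post, FederationConfig)

# 5 edges x 425 rows x 22 features, MCAR 5-30% per column, mild outliers,
# node3 corrupted past the 70% completeness tolerance
corrupted, clean, manifest = standard_corrupted_scenario(seed=1)
baseline = make_baseline_profile(list(clean[0].table.columns))
result = run_federation(corrupted, baseline,
                        FederationConfig(seed=1, max_rounds=1, q_tol=0.0))
r = result.history[0]
print("eliminated:", r.eliminated)
print("selected:", len(r.selected_features), "features")
print("post-repair completeness:", r.completeness)
comp = compare_pre_post(corrupted, result.enriched)
print("federated accuracy %.4f -> %.4f" %
      (comp.federated_before, comp.federated_after))
```

prints

```
eliminated: ['node3']
selected: 15 features
post-repair completeness: 1.0
federated accuracy 0.7666 -> 0.7852
```

The corrupted node fails its completeness tolerance and is excluded from
aggregation; every retained column of every surviving edge is fully
imputed (completeness 1.0); 15 of 22 features survive the rank-sum
selection; and the federated most-similar-patient accuracy rises once the
low-quality node is gone and the repairs are applied.

The same pipeline is scriptable from the shell: `fdqp simulate`,
`fdqp init-baseline`, `fdqp profile-edge`, `fdqp federate`, `fdqp apply`,
`fdqp select-features`, `fdqp evaluate` (see `fdqp --help`).

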