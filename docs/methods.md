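# Methods

## Profile model

A data-quality profile (DQP) is a versioned document (A, W, D, T, R, M)
with three roles: *baseline* (server-issued, version 0), *edge* (baseline
plus locally measured statistics) and *federated* (the server aggregate).
Attribute weights sum to 1 (tolerance 1e−9) and default to uniform 1/D;
the dimension set is stored explicitly and the attribute count is derived
from |A|, avoiding any overloading of "D".  Profiles serialize to a
schema-validated XML dialect (`Profile / Attributes / Attribute /
Tolerances / Measures / Rules / Rule / FederatedFeatures / Workload`; XSD
in `src/fdqp/schema/dqp.xsd`).  Floats are written with Python's shortest
round-trip `repr`, so XML round-trips are bit-exact and profile equality
after a round-trip is plain `==`; `profiles_equal` offers a 1e−9-slack
comparison for pipelines that re-derive numbers.  Version-to-version
deltas are exact patches over a canonical flattened representation:
`apply(old, diff(old, new)) == new` is an identity, property-tested over
generated profiles.  The edge workload stub (config + realtime maps) is
carried opaquely and never interpreted.

## Dimension metrics

Completeness, timeliness and correctness use the standard closed forms
(`1 − MT/NK`, `max(1 − currency/volatility, 0)^s`, `1/(d+1)`).  The
timeliness exponent `s` defaults to 1 and is expert-set.  Uniqueness has
no canonical formula; we use distinct/total over non-missing values, the
usual profiling convention.  Consistency is the per-attribute coefficient
of variation (sample sd over |mean|, n−1 denominator throughout, because
per-edge samples are small), mapped to `1/(1 + mean CV)` for dataset-level
reporting so that "higher is better" aligns with the other dimensions.
Outlier detection defaults to Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(deterministic and robust); a |z| > k detector is available.  Skewness is
the adjusted Fisher–Pearson standardized third moment.  Constant columns
profile as skew 0 (treated as symmetric) rather than erroring, since the
rule engine must still decide their fate.

## Edge profiling and node selection

`build_edge_profile` measures every baseline attribute and inherits
weights, tolerances, rules and version unchanged; it never mutates the
baseline, and measures are row-permutation invariant.  Dataset-level
dimension scores are means over attributes (for completeness this equals
cell-level completeness since all columns share the row count).  A
dimension's tolerance is the mean of the per-attribute tolerances that
configure it; unconfigured or unmeasurable dimensions are skipped with a
warning.  Tolerance comparison passes at equality: tolerances are minimum
acceptable levels, and eliminating a boundary node on float noise would be
spurious.  A fully missing column is profiled degenerate (missing fraction
1, `None` summaries) so the drop rule can handle it.

## Repair rules

Bands anchored by the method: median imputation for skewed attributes at
low missingness, multiple imputation above 20% missing (numeric), column
deletion at high missingness (the worked 70% example).  Defaults chosen to
fill the unspecified gaps: column-drop threshold 0.50, skew cut |skew| > 1,
the skewed→median band extended over the whole (0, 0.20) range (the median
remains the robust choice for skewed data), mode imputation for categorical
columns below 20%.  Categorical columns between 20% and the drop threshold
match no rule and are left untouched with a warning — categorical multiple
imputation is out of scope.  MNAR (value-dependent) missingness has no
given detector; we flag a column when its missing indicator has
|point-biserial r| > 0.3 with any observed column, and route it to KNN
imputation.  Rule ids: 2.1 mean, 2.2 column drop, 2.3 median, 2.4 KNN,
2.5 mode, 2.6 multiple imputation, 2.7 row deletion (2.3/2.5 are
reconstructions, and of the jointly-referenced 2.6/2.7 pair we assign 2.6
to imputation and 2.7 to removal so each id maps to one auditable action).

KNN imputation: Euclidean distance on z-scored predictors, averaged over
the predictor dimensions observed in both rows; donors are rows with the
target observed; ties break to the lower row index (determinism).  Multiple
imputation: OLS of the target on the other numeric attributes over complete
rows, m draws of prediction + N(0, σ̂²) residual noise pooled by mean, with
m = max(5, round(100·mf)) — the 100·mf proportionality constant is a
package default, not derived from the method.  Rows are dropped (with their
labels) when missing in more than 50% of *retained* columns; the row rule
runs after column drops so a hopeless column cannot trigger row deletions,
and only when a dataset-scoped `DROP_ROWS` decision (rule 2.7) is present —
the federation loop always issues one.  Application is idempotent, never
alters observed cells, and leaves retained columns 100% complete whenever
every decision resolves its column.

## Federation

Aggregation semantics (per measure field, configurable): min of minima,
max of maxima, row-count-weighted means for fraction-valued fields, mode
from the largest edge, rule union by id, version = max.  Aggregating a
single edge is the identity and the operation is edge-order invariant.
The per-attribute missing-value vector uses the missing fraction per
attribute over rows (a null count divided by the attribute count is not a
fraction) and its indicator is 1 when the fraction is below the
attribute's ceiling ATol = 1 − completeness tolerance, which reproduces
the canonical example (70% missing vs a 70% completeness tolerance fails).
Attribute fate: weight > 0.5 mandates an imputation regardless of the
indicator; indicator 0 with weight < 0.1 drops the attribute; otherwise
the rule table decides.  Both thresholds are interpreted on raw weights by
default (with weights summing to 1 over many attributes the mandate rarely
fires; that is the faithful reading) and are configuration keys.

Feature selection: per node, feature value = ANOVA F of the feature
against the class label on observed rows (mutual information available as
the alternative scorer); outlier % and missing % come from the node's
profile.  Criteria are summed across nodes *before* ranking; ranks are
permutations of 1..N with ties resolved by stable sort (original feature
order), and the federated rank is the exact integer sum.  Final ordering
ties break by value rank, then outlier, then missing rank.  Selection
happens on profiled (pre-repair) statistics; feature drops and repairs are
then applied together.

The loop carries the enriched datasets forward: round r profiles the data
as repaired by round r−1, the baseline for round r+1 is the federated
profile with dropped attributes removed and weights renormalized, and the
loop stops at `q_tol` federated accuracy or `max_rounds` (default 3).
Eliminated nodes stay eliminated.  Federation is simulated in-process;
there is no transport, authentication or scheduling layer.

## Patient-similarity evaluation

The evaluation stand-in for a full similarity-fusion model is a Gaussian
kernel `exp(−‖z_i − z_j‖²/2σ²)` on z-scored features, σ = median pairwise
distance, with leave-one-out most-similar-patient classification (ties to
the lower row index) — chosen because the loop needs a deterministic,
assumption-light accuracy signal, not a competitive classifier.  A
pre/post comparison evaluates corrupted inputs (missing cells mean-filled,
the naive quality-unaware baseline) against the enriched outputs;
eliminated nodes count in the "before" federation only, which is exactly
how a quality-unaware federation would have used them.

## Synthetic cohorts

The generator mirrors the shape of a fetal cardiotocography cohort —
5 edges × 425 rows, 22 numeric features, three imbalanced classes
(N/S/P at 0.78/0.14/0.08) — with class-conditional Gaussian features:
per class and feature a mean is drawn from N(0, class_separation²) and
unit-variance noise with one-factor pairwise correlation 0.5 is added.
The correlation mimics the shared physiological drivers behind monitoring
channels and is what makes neighbour- and regression-based imputation, and
MNAR detection through other columns, meaningful.  class_separation
defaults to 0.4, calibrated once so that clean most-similar-patient
accuracy sits in the published ~85–90% regime.  Real feature semantics
(FHR baselines, decelerations, histogram features) are deliberately not
reproduced: passing tests show the pipeline's behavior under controlled
Gaussian structure, not performance on clinical data.

Missingness mechanisms: MCAR (per-cell Bernoulli), MAR (logistic in the
z-score of the cyclically next column, slope 2, intercept solved so the
realized mean matches the target rate), MNAR (logistic in the cell's own
value).  Outlier injection displaces cells beyond the nearer Tukey fence
by scale × IQR and returns exact bookkeeping.  Node corruption blanks
exactly ⌈rate·n⌉ cells per column with rate = min(0.97, 1.2·severity +
0.05) — strictly above `severity`, so completeness is guaranteed below
1 − severity and a severity ≥ 0.35 node deterministically fails a 0.70
completeness tolerance — plus heavy Gaussian noise on a tenth of the
survivors.  Every operator derives an independent RNG substream from
(seed, operator name, node id, column) via stable CRC hashing, so adding
one injection never perturbs another.

The standard study condition (`standard_corrupted_scenario`): per-column
MCAR rates drawn from U(0.05, 0.30), outlier rate 0.03 at scale 2.0, and
node3 corrupted at severity 0.4 against a 0.70 completeness tolerance.

## Numerical choices and problem sizes

Weight-sum tolerance 1e−9; measure identities (completeness = 1 − missing
fraction) enforced at 1e−12; seeded `numpy.random.Generator` everywhere,
with derived seeds kept below 2³¹.  Tests run the full pipeline at the
default cohort size (5 × 425 × 22); statistical checks use n = 1000–10000
where a law-of-large-numbers argument needs it, and the directional
accuracy comparison uses 50 seeded replicates of the standard scenario.
Runtime-shape checks compare timings across an 8–16× size span with
generous slack; they assert growth shape, not wall-clock performance.

## Known limitations

- Accuracy/validity against an external gold standard is not measured
  (no real-world reference values exist in the pipeline); the correctness
  metric is exposed for callers that have one.
- No streaming profiling: the "forget already-profiled rows" mechanism is
  represented only as profile bookkeeping.
- No chained-equations imputation framework and no categorical multiple
  imputation.
- The MNAR detector is correlation-based and cannot see purely
  self-dependent missingness in uncorrelated data.
- The similarity model is intentionally minimal; absolute accuracies are
  not comparable to tuned classifiers, only before/after differences under
  identical evaluation are meaningful.
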