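"""Missing-data repair rules: decision logic and application.

The rule table maps a column's measured state (missing fraction, data type,
skew, MNAR evidence) to a concrete repair action.  Default bands:

====  ==========================================  ==================
id    condition                                   action
====  ==========================================  ==================
2.2   missing fraction >= 0.50                    drop the column
2.4   MNAR evidence, missing < 0.50               KNN imputation
2.3   numeric, 0 < missing < 0.20, skewed         median imputation
2.1   numeric, 0 < missing < 0.20, symmetric      mean imputation
2.5   categorical, 0 < missing < 0.20             mode imputation
2.6   numeric, 0.20 <= missing < 0.50             multiple imputation
2.7   row missing in > 50% of retained columns    drop the row
====  ==========================================  ==================

A column with no missing cells needs no rule; a column matching no rule is
left untouched with a warning rather than silently dropped.  All band
thresholds are configuration, not constants: only the "skewed under 5% ->
median", "above 20% numeric -> multiple imputation" and "drop at high
missingness (e.g. 70%)" anchors are fixed by the method; the 0.50 column
drop default and the |skew| > 1 cut reproduce those anchors while filling
the unspecified gaps.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .local_profiler import EdgeDataset
from .profile_model import (
    AttributeMeasures,
    AttributeSpec,
    DataType,
    QualityDimension,
    QualityRule,
    RuleAction,
    RuleCondition,
)

__all__ = [
    "RuleTableConfig",
    "RuleDecision",
    "RepairReport",
    "default_rules",
    "detect_mnar",
    "select_rule",
    "apply_rules",
    "mean_impute",
    "median_impute",
    "mode_impute",
    "knn_impute",
    "multiple_impute",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleTableConfig:
    """Tunable thresholds of the default rule table."""

    column_drop_threshold: float = 0.50  # missing fraction at/above which a column goes
    low_missing_threshold: float = 0.20  # upper bound of the mean/median/mode band
    skew_cut: float = 1.0                # |skew| above this counts as skewed
    mnar_r_threshold: float = 0.3        # |point-biserial r| flagging MNAR
    row_drop_threshold: float = 0.5      # row dropped when missing in > this fraction of columns
    knn_k: int = 5
    mi_m: int | None = None              # None -> max(5, round(100 * missing_fraction))


@dataclass
class RuleDecision:
    attribute: str
    rule_id: str | None
    action: RuleAction
    params: dict = field(default_factory=dict)
    justification: str = ""


@dataclass
class RepairReport:
    decisions: list[RuleDecision] = field(default_factory=list)
    columns_dropped: int = 0
    rows_dropped: int = 0
    cells_imputed: int = 0
    post_completeness: float = 1.0


def default_rules(config: RuleTableConfig = RuleTableConfig()) -> list[QualityRule]:
    """The default missing-data rule table, in matching priority order."""
    c = config
    return [
        QualityRule(
            "2.2", QualityDimension.COMPLETENESS,
            RuleCondition(missing_min=c.column_drop_threshold, missing_max=1.0),
            RuleAction.DROP_COLUMN,
            params={"threshold": c.column_drop_threshold},
        ),
        QualityRule(
            "2.4", QualityDimension.COMPLETENESS,
            RuleCondition(missing_max=c.column_drop_threshold, mnar=True),
            RuleAction.KNN_IMPUTE,
            params={"k": c.knn_k},
        ),
        QualityRule(
            "2.3", QualityDimension.COMPLETENESS,
            RuleCondition(
                missing_max=c.low_missing_threshold,
                data_type=DataType.NUMERIC,
                skew_class="skewed",
            ),
            RuleAction.MEDIAN_IMPUTE,
        ),
        QualityRule(
            "2.1", QualityDimension.COMPLETENESS,
            RuleCondition(
                missing_max=c.low_missing_threshold,
                data_type=DataType.NUMERIC,
                skew_class="symmetric",
            ),
            RuleAction.MEAN_IMPUTE,
        ),
        QualityRule(
            "2.5", QualityDimension.COMPLETENESS,
            RuleCondition(
                missing_max=c.low_missing_threshold,
                data_type=DataType.CATEGORICAL,
            ),
            RuleAction.MODE_IMPUTE,
        ),
        QualityRule(
            "2.6", QualityDimension.COMPLETENESS,
            RuleCondition(
                missing_min=c.low_missing_threshold,
                missing_max=c.column_drop_threshold,
                data_type=DataType.NUMERIC,
            ),
            RuleAction.MULTIPLE_IMPUTE,
        ),
        QualityRule(
            "2.7", QualityDimension.COMPLETENESS,
            # Row-scoped: never matched per attribute; apply_rules reads the
            # threshold parameter directly.
            RuleCondition(missing_min=0.0, missing_max=0.0),
            RuleAction.DROP_ROWS,
            params={"row_missing_threshold": c.row_drop_threshold, "scope": "row"},
        ),
        QualityRule(
            "3.1", QualityDimension.ACCURACY,
            RuleCondition(missing_min=0.0, missing_max=0.0),
            RuleAction.DROP_COLUMN,
            params={"scope": "federated-feature-selection"},
        ),
    ]


def detect_mnar(
    table: pd.DataFrame, attribute: str, r_threshold: float = 0.3
) -> bool:
    """Flag a column whose *missingness* correlates with an observed attribute.

    Point-biserial correlation between the missing indicator and each other
    numeric column; |r| above *r_threshold* for any of them flags systematic
    (non-random) missingness, routed to KNN imputation.
    """
    indicator = table[attribute].isna().to_numpy(float)
    if indicator.std() == 0:
        return False
    for other in table.columns:
        if other == attribute:
            continue
        col = pd.to_numeric(table[other], errors="coerce")
        mask = col.notna().to_numpy()
        if mask.sum() < 3:
            continue
        x = col.to_numpy(float)[mask]
        y = indicator[mask]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) > r_threshold:
            return True
    return False


def select_rule(
    measures: AttributeMeasures,
    spec: AttributeSpec,
    rule_table: list[QualityRule],
    *,
    mnar: bool = False,
    skew_cut: float = 1.0,
) -> RuleDecision:
    """Pick exactly one repair decision for an attribute.

    Rules are tried in table order; the first whose condition matches wins.
    A complete column gets NONE without consulting the table; a column no
    rule covers gets NONE with a warning.
    """
    mf = measures.missing_fraction
    if mf == 0:
        return RuleDecision(
            attribute=spec.name, rule_id=None, action=RuleAction.NONE,
            justification="no missing cells",
        )
    skew = measures.skewness
    skew_class = None
    if skew == skew:  # not NaN
        skew_class = "skewed" if abs(skew) > skew_cut else "symmetric"
    weight = spec.weight if spec.weight is not None else 0.0
    for rule in rule_table:
        if rule.params.get("scope") is not None:
            continue  # row-scoped / federation-scoped rules are not per-attribute
        if rule.condition.matches(mf, spec.data_type, skew_class, weight, mnar):
            return RuleDecision(
                attribute=spec.name,
                rule_id=rule.rule_id,
                action=rule.action,
                params=dict(rule.params),
                justification=(
                    f"missing_fraction={mf:.4g}, data_type={spec.data_type.value}, "
                    f"skew_class={skew_class}, mnar={mnar} matched rule "
                    f"{rule.rule_id} ({rule.action.value})"
                ),
            )
    log.warning(
        "attribute %s: no rule matches (missing_fraction=%.4g, type=%s); "
        "leaving column untouched",
        spec.name, mf, spec.data_type.value,
    )
    return RuleDecision(
        attribute=spec.name, rule_id=None, action=RuleAction.NONE,
        justification=f"no rule matched at missing_fraction={mf:.4g}",
    )


# ---------------------------------------------------------------------------
# Imputers
# ---------------------------------------------------------------------------

def _require_observed(column: pd.Series) -> pd.Series:
    observed = column.dropna()
    if observed.empty:
        raise ValueError("cannot impute an all-missing column")
    return observed


def mean_impute(column: pd.Series) -> pd.Series:
    observed = _require_observed(column)
    return column.fillna(float(pd.to_numeric(observed).mean()))


def median_impute(column: pd.Series) -> pd.Series:
    observed = _require_observed(column)
    return column.fillna(float(pd.to_numeric(observed).median()))


def mode_impute(column: pd.Series) -> pd.Series:
    observed = _require_observed(column)
    return column.fillna(observed.mode().iloc[0])


def _zscore_predictors(
    table: pd.DataFrame, target_attribute: str
) -> tuple[np.ndarray, list[str]]:
    predictors = [
        c for c in table.columns
        if c != target_attribute and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not predictors:
        raise ValueError("no numeric predictor attributes available")
    X = table[predictors].to_numpy(float)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    return (X - mean) / sd, predictors


def knn_impute(dataset: EdgeDataset, target_attribute: str, k: int = 5) -> pd.Series:
    """Replace missing target cells by the mean (numeric) or mode
    (categorical) of the k nearest donor rows.

    Distance is Euclidean on z-scored predictors, averaged over the predictor
    dimensions observed in both rows (so partially missing predictors still
    contribute); ties are broken by lower row index.  Donor rows are those
    with the target observed.
    """
    table = dataset.table
    target = table[target_attribute]
    Z, _ = _zscore_predictors(table, target_attribute)
    donor_idx = np.flatnonzero(target.notna().to_numpy())
    if len(donor_idx) < k:
        raise ValueError(f"need at least k={k} rows with the target observed")
    numeric = pd.api.types.is_numeric_dtype(target)
    result = target.copy()
    target_vals = target.to_numpy()
    for i in np.flatnonzero(target.isna().to_numpy()):
        diff = Z[donor_idx] - Z[i]
        shared = np.isfinite(diff)
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d2 = np.where(
                counts > 0,
                np.nansum(np.where(shared, diff**2, 0.0), axis=1) / np.maximum(counts, 1),
                np.inf,
            )
        order = np.argsort(d2, kind="stable")  # stable: ties -> lower row index
        neighbours = donor_idx[order[:k]]
        vals = pd.Series([target_vals[j] for j in neighbours])
        if numeric:
            result.iloc[i] = float(pd.to_numeric(vals).mean())
        else:
            result.iloc[i] = vals.mode().iloc[0]
    return result


def multiple_impute(
    dataset: EdgeDataset,
    target_attribute: str,
    m: int | None = None,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Pooled stochastic-regression multiple imputation of a numeric target.

    Fits an OLS regression of the target on the other numeric attributes
    using fully observed rows, then draws ``m`` imputations as prediction +
    Gaussian residual noise and pools them by mean.  ``m`` defaults to
    ``max(5, round(100 * missing_fraction))`` — more imputations the more is
    missing.  Returns (pooled column, per-cell imputation standard deviation).
    """
    table = dataset.table
    target = pd.to_numeric(table[target_attribute], errors="raise")
    missing = target.isna().to_numpy()
    mf = missing.mean()
    if m is None:
        m = max(5, round(100 * mf))
    if not missing.any():
        return target.copy(), pd.Series(np.zeros(len(target)), index=target.index)
    Z, predictors = _zscore_predictors(table, target_attribute)
    Zf = np.nan_to_num(Z, nan=0.0)  # z-scored, so 0 = predictor column mean
    X = np.column_stack([np.ones(len(Zf)), Zf])
    complete = (~missing) & np.isfinite(Z).all(axis=1)
    if complete.sum() < 10:
        complete = ~missing  # fall back to mean-filled predictors
    if complete.sum() < 10:
        raise ValueError("need at least 10 complete rows for multiple imputation")
    y = target.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X[complete], y[complete], rcond=None)
    resid = y[complete] - X[complete] @ beta
    dof = max(int(complete.sum()) - X.shape[1], 1)
    sigma = float(np.sqrt((resid**2).sum() / dof))
    rng = np.random.default_rng(seed)
    pred = X[missing] @ beta
    draws = pred[None, :] + rng.normal(0.0, sigma, size=(m, missing.sum()))
    pooled = target.copy()
    pooled.iloc[np.flatnonzero(missing)] = draws.mean(axis=0)
    spread = pd.Series(np.zeros(len(target)), index=target.index)
    spread.iloc[np.flatnonzero(missing)] = draws.std(axis=0, ddof=1) if m > 1 else 0.0
    return pooled, spread


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def apply_rules(
    dataset: EdgeDataset,
    decisions: list[RuleDecision],
    *,
    config: RuleTableConfig = RuleTableConfig(),
    seed: int = 0,
) -> tuple[EdgeDataset, RepairReport]:
    """Apply repair decisions, producing the enriched dataset.

    Order: column drops first (so a hopeless column cannot trigger row
    drops), then the row rule — active only when a ``DROP_ROWS`` decision is
    present (attribute ``"*"`` marks it dataset-scoped), dropping rows
    missing in more than its threshold fraction of the retained columns,
    with matching labels — then imputations.  Observed cells are never
    altered.
    """
    row_decisions = [d for d in decisions if d.action is RuleAction.DROP_ROWS]
    col_decisions = [d for d in decisions if d.action is not RuleAction.DROP_ROWS
                     or d.attribute != "*"]
    by_attr = {d.attribute: d for d in col_decisions}
    unknown = set(by_attr) - set(dataset.table.columns)
    if unknown:
        raise ValueError(f"decisions reference unknown attributes: {sorted(unknown)}")
    not_covered = set(dataset.table.columns) - set(by_attr)
    if not_covered:
        raise ValueError(f"no decision for attributes: {sorted(not_covered)}")

    report = RepairReport(decisions=list(decisions))
    drop_cols = [
        c for c in dataset.table.columns
        if by_attr[c].action is RuleAction.DROP_COLUMN
    ]
    table = dataset.table.drop(columns=drop_cols)
    labels = dataset.labels
    report.columns_dropped = len(drop_cols)

    if row_decisions and len(table.columns) > 0:
        threshold = min(
            d.params.get("row_missing_threshold", config.row_drop_threshold)
            for d in row_decisions
        )
        row_missing = table.isna().mean(axis=1).to_numpy()
        keep = row_missing <= threshold
        report.rows_dropped = int((~keep).sum())
        table = table.loc[keep].reset_index(drop=True)
        labels = labels.loc[keep].reset_index(drop=True)

    missing_before = int(table.isna().sum().sum())
    enriched = table.copy()
    tmp = EdgeDataset(dataset.node_id, enriched, labels)
    for col in enriched.columns:
        decision = by_attr[col]
        action = decision.action
        if action in (RuleAction.NONE, RuleAction.DROP_ROWS):
            continue
        if not enriched[col].isna().any():
            continue
        if action is RuleAction.MEAN_IMPUTE:
            enriched[col] = mean_impute(enriched[col])
        elif action is RuleAction.MEDIAN_IMPUTE:
            enriched[col] = median_impute(enriched[col])
        elif action is RuleAction.MODE_IMPUTE:
            enriched[col] = mode_impute(enriched[col])
        elif action is RuleAction.KNN_IMPUTE:
            k = int(decision.params.get("k", config.knn_k))
            enriched[col] = knn_impute(tmp, col, k=k)
        elif action is RuleAction.MULTIPLE_IMPUTE:
            m = decision.params.get("m", config.mi_m)
            col_seed = (seed * 100003 + zlib.crc32(col.encode())) % (2**31)
            enriched[col], _ = multiple_impute(tmp, col, m=m, seed=col_seed)
        else:  # pragma: no cover - closed enumeration
            raise ValueError(f"unhandled action {action}")
    missing_after = int(enriched.isna().sum().sum())
    report.cells_imputed = missing_before - missing_after
    total_cells = enriched.size
    report.post_completeness = (
        1.0 - missing_after / total_cells if total_cells else 1.0
    )
    return EdgeDataset(dataset.node_id, enriched, labels), report
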