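"""Server-side profile federation.

Implements the federated half of the profiling loop: aggregating edge
profiles into the federated profile (group aggregation with per-field
min / max / weighted-mean semantics), the per-attribute missing-value
vector and its tolerance indicator, attribute-fate decisions driven by
weight and tolerance, elimination of nodes whose quality dimensions fall
below tolerance, rank-sum federated feature selection, and the versioned
round loop that stops when the federated patient-similarity accuracy
reaches the target.

Only profiles and accuracy scores cross the (simulated) network boundary;
edge tables stay inside their :class:`~fdqp.local_profiler.EdgeDataset`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import psn_eval
from .local_profiler import (
    EdgeDataset,
    ToleranceReport,
    build_edge_profile,
    check_dimension_tolerances,
    dataset_dimension_scores,
)
from .profile_model import (
    AttributeMeasures,
    AttributeSpec,
    DataType,
    DQProfile,
    ProfileRole,
    QualityDimension,
    QualityRule,
    RuleAction,
    diff_profiles,
    initialize_profile,
    normalize_weights,
)
from .rule_engine import (
    RuleDecision,
    RuleTableConfig,
    apply_rules,
    default_rules,
    detect_mnar,
    select_rule,
)

__all__ = [
    "FederationError",
    "FederationConfig",
    "AttributeFate",
    "MissingValueVector",
    "FeatureRankTable",
    "RoundRecord",
    "FederationResult",
    "make_baseline_profile",
    "missing_value_vector",
    "aggregate_profiles",
    "decide_attribute_fate",
    "select_nodes",
    "compute_feature_stats",
    "combine_ranks",
    "federated_feature_selection",
    "run_federation",
]


class FederationError(RuntimeError):
    """Raised when federation cannot proceed (e.g. every node eliminated)."""


_DEFAULT_AGG = {
    "observed_min": "min",
    "observed_max": "max",
    "missing_fraction": "weighted_mean",
    "unique_fraction": "weighted_mean",
    "outlier_fraction": "weighted_mean",
    "skewness": "weighted_mean",
    "cv": "weighted_mean",
}


@dataclass
class FederationConfig:
    """Loop and aggregation configuration.

    ``q_tol`` is the target federated accuracy that stops the loop,
    ``feature_tol`` the maximum number of features kept by federated
    feature selection, and the two weight thresholds drive attribute fate:
    above ``weight_impute_threshold`` an imputation is mandated regardless
    of the tolerance indicator, below ``weight_insignificance_threshold``
    an attribute that also fails its tolerance is removed.
    """

    q_tol: float = 0.9
    feature_tol: int = 15
    max_rounds: int = 3
    agg_spec: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_AGG))
    weight_impute_threshold: float = 0.5
    weight_insignificance_threshold: float = 0.1
    feature_scorer: str = "anova"  # "anova" | "mutual_info"
    rule_config: RuleTableConfig = field(default_factory=RuleTableConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_tol <= 1.0:
            raise ValueError("q_tol must lie in [0, 1]")
        if self.feature_tol < 1:
            raise ValueError("feature_tol must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


class AttributeFate(Enum):
    FORCE_IMPUTE = "force_impute"
    DROP = "drop"
    RETAIN = "retain"


@dataclass
class MissingValueVector:
    """Per-attribute missing fraction plus its tolerance indicator
    (1 = within tolerance, 0 = violates it)."""

    mv: dict[str, float]
    indicator: dict[str, int]


def make_baseline_profile(
    feature_names: Sequence[str],
    *,
    completeness_tolerance: float = 0.70,
    weights: Sequence[float] | None = None,
    dimensions: Sequence[QualityDimension] = (
        QualityDimension.COMPLETENESS,
        QualityDimension.CONSISTENCY,
        QualityDimension.UNIQUENESS,
    ),
    rule_config: RuleTableConfig = RuleTableConfig(),
) -> DQProfile:
    """Baseline profile over numeric attributes with the default rule table
    and a shared completeness tolerance (default: the conventional 70%)."""
    specs = [
        AttributeSpec(
            name=name,
            data_type=DataType.NUMERIC,
            weight=None if weights is None else float(weights[i]),
            tolerances={QualityDimension.COMPLETENESS: completeness_tolerance},
        )
        for i, name in enumerate(feature_names)
    ]
    return initialize_profile(specs, dimensions, default_rules(rule_config))


def _atol(spec: AttributeSpec) -> float:
    """Missing-fraction ceiling for an attribute: 1 - completeness tolerance."""
    if QualityDimension.COMPLETENESS not in spec.tolerances:
        raise FederationError(
            f"attribute {spec.name} lacks a completeness (missing-data) tolerance"
        )
    return 1.0 - spec.tolerances[QualityDimension.COMPLETENESS]


def missing_value_vector(edge_profile: DQProfile) -> MissingValueVector:
    """Per-attribute missing fractions and their tolerance indicators."""
    if edge_profile.measures is None:
        raise ValueError("profile has no measures")
    mv: dict[str, float] = {}
    indicator: dict[str, int] = {}
    for spec in edge_profile.attributes:
        frac = edge_profile.measures[spec.name].missing_fraction
        mv[spec.name] = frac
        indicator[spec.name] = 1 if frac < _atol(spec) else 0
    return MissingValueVector(mv=mv, indicator=indicator)


def _agg_values(values: list, weights: list[float], how: str):
    pairs = [
        (v, w) for v, w in zip(values, weights)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not pairs:
        return math.nan if how == "weighted_mean" else None
    vals = [p[0] for p in pairs]
    if how == "min":
        return min(vals)
    if how == "max":
        return max(vals)
    if how == "sum":
        return float(sum(vals))
    if how == "weighted_mean":
        ws = np.array([p[1] for p in pairs], float)
        return float(np.average(np.array(vals, float), weights=ws))
    raise ValueError(f"unknown aggregation {how!r}")


def aggregate_profiles(
    edge_profiles: Sequence[DQProfile], config: FederationConfig | None = None
) -> DQProfile:
    """Group-aggregate edge profiles into the federated profile.

    Minima take the min, maxima the max, fraction-valued measures the
    row-count-weighted mean (a single edge therefore aggregates to itself);
    the mode is taken from the largest edge; rules are unioned by id and the
    version is the max input version.
    """
    if not edge_profiles:
        raise FederationError("cannot aggregate an empty profile list")
    config = config or FederationConfig()
    names0 = [s.name for s in edge_profiles[0].attributes]
    for p in edge_profiles[1:]:
        if [s.name for s in p.attributes] != names0:
            raise FederationError("edge profiles have mismatched attribute sets")
        if p.measures is None:
            raise FederationError(f"edge profile {p.node_id} has no measures")
    if edge_profiles[0].measures is None:
        raise FederationError(f"edge profile {edge_profiles[0].node_id} has no measures")

    fed = edge_profiles[0].copy()
    fed.role = ProfileRole.FEDERATED
    fed.node_id = None
    fed.workload = None
    fed.version = max(p.version for p in edge_profiles)
    fed.row_count = sum(p.row_count for p in edge_profiles)
    weights = [float(p.row_count) for p in edge_profiles]
    if sum(weights) == 0:
        weights = [1.0] * len(edge_profiles)
    largest = max(range(len(edge_profiles)), key=lambda i: weights[i])

    fed.measures = {}
    for name in names0:
        ms = [p.measures[name] for p in edge_profiles]  # type: ignore[index]
        agg = AttributeMeasures()
        for fname, how in config.agg_spec.items():
            setattr(agg, fname, _agg_values([getattr(m, fname) for m in ms], weights, how))
        if isinstance(agg.skewness, float) or agg.skewness is None:
            agg.skewness = agg.skewness if agg.skewness is not None else math.nan
        agg.completeness = 1.0 - agg.missing_fraction
        agg.mode = ms[largest].mode
        fed.measures[name] = agg

    seen = {r.rule_id for r in fed.rules}
    for p in edge_profiles[1:]:
        for rule in p.rules:
            if rule.rule_id not in seen:
                fed.rules.append(rule)
                seen.add(rule.rule_id)
    return fed


def decide_attribute_fate(
    indicator: int, weight: float, config: FederationConfig
) -> AttributeFate:
    """Weight/tolerance arbitration for one attribute after aggregation."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if weight > config.weight_impute_threshold:
        return AttributeFate.FORCE_IMPUTE
    if indicator == 0 and weight < config.weight_insignificance_threshold:
        return AttributeFate.DROP
    return AttributeFate.RETAIN


def select_nodes(
    edge_profiles: Sequence[DQProfile],
) -> tuple[list[DQProfile], list[DQProfile], dict[str, ToleranceReport]]:
    """Split nodes into (selected, eliminated) by their tolerance reports."""
    selected: list[DQProfile] = []
    eliminated: list[DQProfile] = []
    reports: dict[str, ToleranceReport] = {}
    for profile in edge_profiles:
        report = check_dimension_tolerances(profile)
        reports[profile.node_id or ""] = report
        (selected if report.overall_pass else eliminated).append(profile)
    if not selected:
        raise FederationError("every node failed its quality tolerances")
    return selected, eliminated, reports


# ---------------------------------------------------------------------------
# Federated feature selection
# ---------------------------------------------------------------------------

def compute_feature_stats(
    dataset: EdgeDataset,
    edge_profile: DQProfile,
    scorer: str = "anova",
    seed: int = 0,
) -> pd.DataFrame:
    """One node's per-feature selection criteria.

    ``feature_value`` scores the feature against the class label (ANOVA F
    by default, mutual information as the alternative); outlier and missing
    percentages come from the node's measured profile.
    """
    if edge_profile.measures is None:
        raise ValueError("edge profile has no measures")
    features = [s.name for s in edge_profile.attributes]
    if scorer == "anova":
        values = []
        y = dataset.labels.to_numpy()
        for name in features:
            col = pd.to_numeric(dataset.table[name], errors="coerce")
            mask = col.notna().to_numpy()
            groups = [
                col.to_numpy(float)[mask & (y == cls)]
                for cls in pd.unique(y)
            ]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                values.append(0.0)
                continue
            f, _ = sps.f_oneway(*groups)
            values.append(float(f) if math.isfinite(f) else 0.0)
    elif scorer == "mutual_info":
        from sklearn.feature_selection import mutual_info_classif

        filled = dataset.table[features].apply(
            lambda c: pd.to_numeric(c, errors="coerce")
        )
        filled = filled.fillna(filled.mean()).fillna(0.0)
        values = mutual_info_classif(
            filled.to_numpy(float), dataset.labels.to_numpy(), random_state=seed
        ).tolist()
    else:
        raise ValueError(f"unknown feature scorer {scorer!r}")
    return pd.DataFrame(
        {
            "feature_value": values,
            "outlier_pct": [
                edge_profile.measures[n].outlier_fraction for n in features
            ],
            "missing_pct": [
                edge_profile.measures[n].missing_fraction for n in features
            ],
        },
        index=pd.Index(features, name="feature"),
    )


@dataclass
class FeatureRankTable:
    """Per-feature criterion ranks, their exact sum, and the selection flag.

    ``table`` is indexed by feature with integer columns ``value_rank``,
    ``outlier_rank``, ``missing_rank``, ``federated_rank`` and boolean
    ``selected``; ``ordering`` lists features best-first.
    """

    table: pd.DataFrame
    ordering: list[str]

    @property
    def selected(self) -> list[str]:
        return [f for f in self.ordering if bool(self.table.loc[f, "selected"])]


def _permutation_rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    """Ranks 1..N; ties resolved by original position (stable sort)."""
    keys = values if ascending else -values
    order = np.argsort(keys, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def combine_ranks(
    rank_columns: pd.DataFrame, feature_tol: int | None = None
) -> FeatureRankTable:
    """Sum already-assigned criterion ranks into the federated rank.

    Expects integer columns ``value_rank``, ``outlier_rank`` and
    ``missing_rank``; the federated rank is their exact sum, features are
    ordered ascending by it with ties broken by value, then outlier, then
    missing rank, and the best ``feature_tol`` features are marked selected.
    """
    table = rank_columns[["value_rank", "outlier_rank", "missing_rank"]].copy()
    table["federated_rank"] = (
        table["value_rank"] + table["outlier_rank"] + table["missing_rank"]
    )
    position = {f: i for i, f in enumerate(table.index)}
    ordering = sorted(
        table.index,
        key=lambda f: (
            table.loc[f, "federated_rank"],
            table.loc[f, "value_rank"],
            table.loc[f, "outlier_rank"],
            table.loc[f, "missing_rank"],
            position[f],
        ),
    )
    k = len(table) if feature_tol is None else min(feature_tol, len(table))
    chosen = set(ordering[:k])
    table["selected"] = [f in chosen for f in table.index]
    return FeatureRankTable(table=table, ordering=list(ordering))


def federated_feature_selection(
    per_node_stats: Sequence[pd.DataFrame], feature_tol: int
) -> FeatureRankTable:
    """Rank-sum feature selection across nodes.

    Criteria are summed across nodes first; then rank 1 goes to the largest
    summed feature value, the smallest summed outlier percentage and the
    smallest summed missing percentage respectively, and the three ranks are
    summed into the federated rank (lower = better).
    """
    if not per_node_stats:
        raise FederationError("no per-node feature statistics")
    index0 = list(per_node_stats[0].index)
    for df in per_node_stats[1:]:
        if list(df.index) != index0:
            raise FederationError("inconsistent feature sets across nodes")
    agg = sum(df[["feature_value", "outlier_pct", "missing_pct"]] for df in per_node_stats)
    ranks = pd.DataFrame(
        {
            "value_rank": _permutation_rank(
                agg["feature_value"].to_numpy(float), ascending=False
            ),
            "outlier_rank": _permutation_rank(
                agg["outlier_pct"].to_numpy(float), ascending=True
            ),
            "missing_rank": _permutation_rank(
                agg["missing_pct"].to_numpy(float), ascending=True
            ),
        },
        index=agg.index,
    )
    return combine_ranks(ranks, feature_tol)


# ---------------------------------------------------------------------------
# The federation loop
# ---------------------------------------------------------------------------

@dataclass
class RoundRecord:
    version: int
    eliminated: list[str]
    selected_features: list[str]
    dropped_attributes: list[str]
    completeness: float
    consistency: float
    per_edge_accuracy: dict[str, float]
    federated_accuracy: float
    delta_fields: int | None = None


@dataclass
class FederationResult:
    profile: DQProfile
    enriched: list[EdgeDataset]
    history: list[RoundRecord]
    rank_table: FeatureRankTable | None = None


def _reduced_baseline(fed: DQProfile, dropped: set[str]) -> DQProfile:
    nxt = fed.copy()
    nxt.role = ProfileRole.BASELINE
    nxt.node_id = None
    nxt.measures = None
    nxt.selected_features = None
    nxt.attributes = [s for s in nxt.attributes if s.name not in dropped]
    if not nxt.attributes:
        raise FederationError("every attribute was dropped")
    ws = normalize_weights([s.weight for s in nxt.attributes])
    for s, w in zip(nxt.attributes, ws):
        s.weight = w
    return nxt


def run_federation(
    edges: Sequence[EdgeDataset],
    baseline: DQProfile,
    config: FederationConfig | None = None,
) -> FederationResult:
    """Run the versioned profiling loop over in-process edges.

    Each round: broadcast the profile, build edge profiles, eliminate nodes
    below tolerance, aggregate the survivors, select features, derive repair
    decisions from the aggregated measures (weight mandates included), apply
    them at every surviving edge, and evaluate the federated
    most-similar-patient accuracy.  The loop stops when that accuracy
    reaches ``q_tol`` or after ``max_rounds``; after the first round the
    history records how many profile fields the round's delta touched.
    """
    if len(edges) < 2:
        raise FederationError("federation needs at least 2 edges")
    config = config or FederationConfig()
    current = baseline.copy()
    datasets: dict[str, EdgeDataset] = {e.node_id: e for e in edges}
    history: list[RoundRecord] = []
    prev_fed: DQProfile | None = None
    fed: DQProfile | None = None
    rank_table: FeatureRankTable | None = None

    for _round in range(1, config.max_rounds + 1):
        profiles = [
            build_edge_profile(datasets[nid], current) for nid in datasets
        ]
        selected_profiles, eliminated_profiles, _reports = select_nodes(profiles)
        eliminated_ids = [p.node_id or "" for p in eliminated_profiles]
        for nid in eliminated_ids:
            datasets.pop(nid, None)

        fed = aggregate_profiles(selected_profiles, config)
        fed.version = current.version + 1

        stats = [
            compute_feature_stats(
                datasets[p.node_id], p, config.feature_scorer, config.seed
            )
            for p in selected_profiles
        ]
        rank_table = federated_feature_selection(stats, config.feature_tol)
        fed.selected_features = rank_table.selected
        keep = set(fed.selected_features)

        mvv = missing_value_vector(fed)
        decisions: list[RuleDecision] = []
        dropped: list[str] = []
        for spec in fed.attributes:
            m = fed.measures[spec.name]  # type: ignore[index]
            if spec.name not in keep:
                decisions.append(
                    RuleDecision(
                        attribute=spec.name,
                        rule_id="3.1",
                        action=RuleAction.DROP_COLUMN,
                        justification="eliminated by federated feature selection",
                    )
                )
                dropped.append(spec.name)
                continue
            fate = decide_attribute_fate(
                mvv.indicator[spec.name], spec.weight or 0.0, config
            )
            if fate is AttributeFate.DROP:
                decisions.append(
                    RuleDecision(
                        attribute=spec.name,
                        rule_id="2.2",
                        action=RuleAction.DROP_COLUMN,
                        justification=(
                            "insignificant weight and missing fraction above "
                            "tolerance"
                        ),
                    )
                )
                dropped.append(spec.name)
                continue
            mnar = any(
                detect_mnar(
                    datasets[p.node_id].table,
                    spec.name,
                    config.rule_config.mnar_r_threshold,
                )
                for p in selected_profiles
            )
            decision = select_rule(
                m, spec, fed.rules, mnar=mnar,
                skew_cut=config.rule_config.skew_cut,
            )
            if fate is AttributeFate.FORCE_IMPUTE and decision.action in (
                RuleAction.NONE, RuleAction.DROP_COLUMN,
            ) and m.missing_fraction > 0:
                decision = RuleDecision(
                    attribute=spec.name,
                    rule_id="2.1",
                    action=RuleAction.MEAN_IMPUTE,
                    justification="imputation mandated by attribute weight",
                )
            if decision.action is RuleAction.DROP_COLUMN:
                dropped.append(spec.name)
            decisions.append(decision)
        decisions.append(
            RuleDecision(
                attribute="*",
                rule_id="2.7",
                action=RuleAction.DROP_ROWS,
                params={
                    "row_missing_threshold": config.rule_config.row_drop_threshold
                },
                justification="federated row-deletion threshold",
            )
        )

        enriched: dict[str, EdgeDataset] = {}
        accs: list[float] = []
        counts: list[int] = []
        per_edge_acc: dict[str, float] = {}
        for nid in list(datasets):
            seed = (
                config.seed * 1009 + _round * 31 + zlib.crc32(nid.encode())
            ) % (2**31)
            enriched_ds, _report = apply_rules(
                datasets[nid], decisions, config=config.rule_config, seed=seed
            )
            enriched[nid] = enriched_ds
            acc = psn_eval.edge_accuracy(enriched_ds)
            if not math.isfinite(acc):
                raise FederationError(f"non-finite accuracy at node {nid}")
            per_edge_acc[nid] = acc
            accs.append(acc)
            counts.append(enriched_ds.n_rows)
        fed_score = psn_eval.federated_accuracy(accs, counts)

        scores = {}
        for p in selected_profiles:
            scores[p.node_id] = dataset_dimension_scores(p)
        delta_fields = (
            len(diff_profiles(prev_fed, fed).changed_fields)
            if prev_fed is not None
            else None
        )
        enriched_scores = [
            1.0 - enriched[nid].table.isna().mean().mean() for nid in enriched
        ]
        cons = float(
            np.mean(
                [
                    s.get(QualityDimension.CONSISTENCY, math.nan)
                    for s in scores.values()
                ]
            )
        )
        history.append(
            RoundRecord(
                version=fed.version,
                eliminated=eliminated_ids,
                selected_features=list(fed.selected_features),
                dropped_attributes=dropped,
                completeness=float(np.mean(enriched_scores)),
                consistency=cons,
                per_edge_accuracy=per_edge_acc,
                federated_accuracy=fed_score.federated_accuracy,
            )
        )
        history[-1].delta_fields = delta_fields

        datasets = enriched
        prev_fed = fed
        if fed_score.federated_accuracy >= config.q_tol:
            break
        current = _reduced_baseline(fed, set(dropped))

    return FederationResult(
        profile=fed,  # type: ignore[arg-type]
        enriched=list(datasets.values()),
        history=history,
        rank_table=rank_table,
    )
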