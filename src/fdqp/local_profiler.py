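"""Edge-side profiling: build a local DQP against the baseline profile.

An edge node never ships its data; it ships a profile.  ``build_edge_profile``
measures every baseline attribute on the local table (min/max/mode, skewness,
missing/unique/outlier fractions, coefficient of variation) and
``check_dimension_tolerances`` compares the resulting dataset-level dimension
scores against the baseline tolerances — the server eliminates nodes whose
report fails.

Measured-vs-tolerance comparison passes at equality: tolerances are minimum
acceptable levels, and eliminating a node over float noise at the boundary
would be spurious.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .profile_model import (
    AttributeMeasures,
    AttributeSpec,
    DataType,
    DQProfile,
    ProfileRole,
    QualityDimension,
    WorkloadStub,
)

__all__ = [
    "EdgeDataset",
    "DimensionCheck",
    "ToleranceReport",
    "profile_attribute",
    "build_edge_profile",
    "dataset_dimension_scores",
    "check_dimension_tolerances",
]

log = logging.getLogger(__name__)


@dataclass
class EdgeDataset:
    """One node's labeled table: features in ``table``, one label per row."""

    node_id: str
    table: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.table):
            raise ValueError("label count must equal row count")
        if self.table.columns.duplicated().any():
            raise ValueError("attribute names must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def copy(self) -> "EdgeDataset":
        return EdgeDataset(self.node_id, self.table.copy(), self.labels.copy())


@dataclass(frozen=True)
class DimensionCheck:
    measured: float
    tolerance: float
    passed: bool


@dataclass
class ToleranceReport:
    node_id: str | None
    per_dimension: dict[QualityDimension, DimensionCheck] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.per_dimension.values())


def profile_attribute(column: pd.Series, spec: AttributeSpec) -> AttributeMeasures:
    """Measure one column.  All-missing columns come back degenerate
    (missing_fraction 1, ``None``/NaN summaries) rather than erroring, so the
    rule engine can still decide to drop them."""
    n = len(column)
    if n == 0:
        raise ValueError("cannot profile an empty column")
    missing = int(column.isna().sum())
    mf = missing / n
    m = AttributeMeasures(missing_fraction=mf, completeness=1.0 - mf)
    observed = column.dropna()
    if observed.empty:
        m.unique_fraction = 0.0
        return m
    m.unique_fraction = metrics.uniqueness_metric(observed)
    modes = observed.mode()
    m.mode = modes.iloc[0] if not modes.empty else None
    if spec.data_type is DataType.NUMERIC:
        values = pd.to_numeric(observed)
        m.observed_min = float(values.min())
        m.observed_max = float(values.max())
        if m.mode is not None:
            m.mode = float(m.mode)
        if len(values) >= 3 and values.std(ddof=1) > 0:
            m.skewness = metrics.skewness(values)
        elif len(values) >= 3:
            m.skewness = 0.0  # constant column: treated as symmetric
        if len(values) >= 4:
            m.outlier_fraction = metrics.outlier_fraction(values)
        if len(values) >= 2 and values.mean() != 0:
            m.cv = metrics.consistency_cv(values)
    else:
        m.observed_min = min(observed)
        m.observed_max = max(observed)
    return m


def build_edge_profile(
    dataset: EdgeDataset,
    baseline: DQProfile,
    workload: WorkloadStub | None = None,
) -> DQProfile:
    """Apply the baseline profile to local data, producing the edge profile.

    Weights, tolerances, rules and the version are inherited unchanged; only
    role, node identity, row count and the measures differ.  The baseline is
    never mutated.
    """
    if baseline.role is not ProfileRole.BASELINE:
        raise ValueError(f"expected a baseline profile, got role {baseline.role.value}")
    missing_attrs = [
        s.name for s in baseline.attributes if s.name not in dataset.table.columns
    ]
    if missing_attrs:
        raise ValueError(f"dataset lacks baseline attributes: {missing_attrs}")
    profile = baseline.copy()
    profile.role = ProfileRole.EDGE
    profile.node_id = dataset.node_id
    profile.row_count = dataset.n_rows
    profile.workload = workload
    profile.measures = {
        spec.name: profile_attribute(dataset.table[spec.name], spec)
        for spec in profile.attributes
    }
    return profile


def dataset_dimension_scores(profile: DQProfile) -> dict[QualityDimension, float]:
    """Dataset-level scores for the dimensions a profile can measure.

    completeness: mean attribute completeness (= cell-level completeness,
    all columns sharing the row count); uniqueness: mean unique fraction;
    consistency: ``1/(1 + mean CV)`` so that higher is better, like the
    other dimensions.
    """
    if profile.measures is None:
        raise ValueError("profile has no measures")
    ms = [profile.measures[s.name] for s in profile.attributes]
    scores: dict[QualityDimension, float] = {}
    scores[QualityDimension.COMPLETENESS] = float(
        np.mean([m.completeness for m in ms])
    )
    scores[QualityDimension.UNIQUENESS] = float(
        np.mean([m.unique_fraction for m in ms])
    )
    cvs = [m.cv for m in ms if m.cv is not None and math.isfinite(m.cv)]
    if cvs:
        scores[QualityDimension.CONSISTENCY] = metrics.consistency_score(
            float(np.mean(cvs))
        )
    return scores


def check_dimension_tolerances(edge_profile: DQProfile) -> ToleranceReport:
    """Compare the profile's dataset-level dimension scores to its tolerances.

    A dimension's tolerance is the mean of the per-attribute tolerances that
    configure it; dimensions with no tolerance, or no measurable score, are
    skipped with a warning.  Pass iff measured >= tolerance.
    """
    scores = dataset_dimension_scores(edge_profile)
    report = ToleranceReport(node_id=edge_profile.node_id)
    for dim in sorted(edge_profile.dimensions, key=lambda d: d.value):
        tols = [
            s.tolerances[dim] for s in edge_profile.attributes if dim in s.tolerances
        ]
        if not tols:
            log.warning(
                "node %s: dimension %s has no tolerance configured; skipped",
                edge_profile.node_id, dim.value,
            )
            continue
        if dim not in scores:
            log.warning(
                "node %s: dimension %s has no measured score; skipped",
                edge_profile.node_id, dim.value,
            )
            continue
        tolerance = float(np.mean(tols))
        measured = scores[dim]
        report.per_dimension[dim] = DimensionCheck(
            measured=measured, tolerance=tolerance, passed=measured >= tolerance
        )
    return report
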