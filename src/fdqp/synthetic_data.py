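"""Synthetic multi-edge cohorts with controlled quality defects.

Emulates the shape of a fetal cardiotocography monitoring cohort —
about 2126 rows split evenly over 5 edge nodes, 22 numeric features and a
3-class imbalanced fetal-state label (normal / suspect / pathologic,
roughly 0.78 / 0.14 / 0.08) — without reproducing any real feature
semantics.  Features are class-conditional Gaussians: per class and
feature, a mean is drawn from N(0, class_separation^2) and unit-variance
noise with pairwise correlation ``feature_correlation`` (a one-factor
structure, mimicking the shared physiological drivers behind monitoring
channels) is added; every edge draws from the same distribution (the
i.i.d.-edges assumption of the federation model).  The correlation is what
makes neighbour- and regression-based imputation — and the detection of
value-dependent missingness through *other* columns — meaningful at all.

Corruption operators (missingness by MCAR/MAR/MNAR mechanism, fence-busting
outliers, whole-node degradation) are pure functions of (spec, seed); each
operator derives its own substream from the global seed and stable hashes
of the operator name and node id, so adding one injection never perturbs
another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .local_profiler import EdgeDataset

__all__ = [
    "CohortSpec",
    "CorruptionSpec",
    "generate_cohort",
    "inject_missing",
    "inject_outliers",
    "corrupt_node",
    "standard_corrupted_scenario",
]

_CLASS_NAMES_3 = ("N", "S", "P")


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Substream derived from the global seed and stable token hashes."""
    entropy = [int(seed) % 2**31] + [
        zlib.crc32(str(t).encode()) for t in tokens
    ]
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class CohortSpec:
    n_edges: int = 5
    rows_per_edge: int = 425
    n_features: int = 22
    class_proportions: tuple[float, ...] = (0.78, 0.14, 0.08)
    class_separation: float = 0.4
    feature_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_edges, self.rows_per_edge, self.n_features) <= 0:
            raise ValueError("all counts must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")


@dataclass(frozen=True)
class CorruptionSpec:
    missing_mechanism: str = "MCAR"  # MCAR | MAR | MNAR
    missing_rates: Mapping[str, float] | float = 0.1
    outlier_rate: float = 0.0
    outlier_scale: float = 2.0
    corrupted_node: str | None = None
    corruption_severity: float = 0.4

    def __post_init__(self) -> None:
        rates = (
            list(self.missing_rates.values())
            if isinstance(self.missing_rates, Mapping)
            else [self.missing_rates]
        )
        for r in rates + [self.outlier_rate]:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


def generate_cohort(spec: CohortSpec) -> list[EdgeDataset]:
    """Draw the full i.i.d. cohort and split it sequentially into edges."""
    rng = _rng(spec.seed, "cohort")
    n_classes = len(spec.class_proportions)
    total = spec.n_edges * spec.rows_per_edge
    means = rng.normal(
        0.0, spec.class_separation, size=(n_classes, spec.n_features)
    )
    labels = rng.choice(n_classes, size=total, p=spec.class_proportions)
    rho = spec.feature_correlation
    shared = rng.standard_normal((total, 1))
    noise = (
        math.sqrt(rho) * shared
        + math.sqrt(1.0 - rho) * rng.standard_normal((total, spec.n_features))
    )
    X = means[labels] + noise
    columns = [f"f{j + 1:02d}" for j in range(spec.n_features)]
    if n_classes == 3:
        label_names = np.array(_CLASS_NAMES_3)[labels]
    else:
        label_names = np.array([f"C{c + 1}" for c in range(n_classes)])[labels]
    edges = []
    for e in range(spec.n_edges):
        sl = slice(e * spec.rows_per_edge, (e + 1) * spec.rows_per_edge)
        edges.append(
            EdgeDataset(
                node_id=f"node{e + 1}",
                table=pd.DataFrame(X[sl], columns=columns),
                labels=pd.Series(label_names[sl], name="fetal_state"),
            )
        )
    return edges


def _logistic_probs(z: np.ndarray, rate: float, slope: float = 2.0) -> np.ndarray:
    """Per-row missingness probabilities sigmoid(a + slope*z) with the
    intercept calibrated so the empirical mean equals *rate*."""
    if rate <= 0:
        return np.zeros_like(z)
    if rate >= 1:
        return np.ones_like(z)

    def gap(a: float) -> float:
        return float(expit(a + slope * z).mean() - rate)

    a = brentq(gap, -40.0, 40.0)
    return expit(a + slope * z)


def inject_missing(
    dataset: EdgeDataset, spec: CorruptionSpec, seed: int
) -> tuple[EdgeDataset, dict[str, float]]:
    """Blank cells per column at the requested rate under the requested
    mechanism; returns the corrupted copy and the realized per-column rates.

    MCAR: independent Bernoulli per cell.  MAR: probability logistic in the
    z-score of the *next* feature column (cyclically).  MNAR: logistic in the
    cell's own z-scored value — systematically missing where values are high.
    """
    if spec.missing_mechanism not in ("MCAR", "MAR", "MNAR"):
        raise ValueError(f"unknown mechanism {spec.missing_mechanism!r}")
    table = dataset.table.copy()
    cols = list(table.columns)
    rates = (
        dict(spec.missing_rates)
        if isinstance(spec.missing_rates, Mapping)
        else {c: float(spec.missing_rates) for c in cols}
    )
    realized: dict[str, float] = {}
    n = len(table)
    for col, rate in rates.items():
        if rate == 0:
            realized[col] = 0.0
            continue
        rng = _rng(seed, "missing", dataset.node_id, col)
        values = table[col].to_numpy(float)
        if spec.missing_mechanism == "MCAR":
            probs = np.full(n, rate)
        else:
            if spec.missing_mechanism == "MNAR":
                driver = values
            else:  # MAR: driven by another observed column
                other = cols[(cols.index(col) + 1) % len(cols)]
                driver = table[other].to_numpy(float) if other != col else values
            sd = float(np.nanstd(driver))
            z = (driver - float(np.nanmean(driver))) / (sd if sd > 0 else 1.0)
            z = np.nan_to_num(z)  # already-missing driver cells act as average
            probs = _logistic_probs(z, rate)
        mask = rng.random(n) < probs
        table.loc[mask, col] = np.nan
        realized[col] = float(mask.mean())
    return EdgeDataset(dataset.node_id, table, dataset.labels.copy()), realized


def inject_outliers(
    dataset: EdgeDataset, rate: float, scale: float, seed: int
) -> tuple[EdgeDataset, list[tuple[int, str, float, float]]]:
    """Displace a *rate* fraction of observed cells beyond the nearer Tukey
    fence by ``scale * IQR``.  Returns the displaced copy and the exact
    bookkeeping list of (row, column, old value, new value)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    table = dataset.table.copy()
    book: list[tuple[int, str, float, float]] = []
    if rate == 0:
        return EdgeDataset(dataset.node_id, table, dataset.labels.copy()), book
    for col in table.columns:
        rng = _rng(seed, "outliers", dataset.node_id, col)
        values = table[col].to_numpy(float)
        observed = np.flatnonzero(np.isfinite(values))
        if observed.size < 4:
            continue
        q1, q3 = np.percentile(values[observed], [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            continue
        median = np.median(values[observed])
        hit = observed[rng.random(observed.size) < rate]
        for i in hit:
            old = values[i]
            if old >= median:
                new = q3 + 1.5 * iqr + scale * iqr
            else:
                new = q1 - 1.5 * iqr - scale * iqr
            table.iloc[i, table.columns.get_loc(col)] = new
            book.append((int(i), col, float(old), float(new)))
    return EdgeDataset(dataset.node_id, table, dataset.labels.copy()), book


def corrupt_node(
    dataset: EdgeDataset, severity: float, seed: int = 0
) -> EdgeDataset:
    """Degrade a whole node: per column, exactly ``ceil(rate * n)`` cells are
    blanked with ``rate = min(0.97, 1.2 * severity + 0.05)``, which pushes the
    dataset completeness strictly below ``1 - severity``; a tenth of the
    surviving cells also receive heavy Gaussian noise.  A node corrupted at
    severity >= 0.35 is guaranteed to fail a 0.70 completeness tolerance."""
    if not 0.0 < severity <= 1.0:
        raise ValueError("severity must lie in (0, 1]")
    rate = min(0.97, 1.2 * severity + 0.05)
    table = dataset.table.copy()
    n = len(table)
    k = math.ceil(rate * n)
    for col in table.columns:
        rng = _rng(seed, "corrupt", dataset.node_id, col)
        loc = table.columns.get_loc(col)
        blank = rng.choice(n, size=min(k, n), replace=False)
        table.iloc[blank, loc] = np.nan
        values = table[col].to_numpy(float)
        observed = np.flatnonzero(np.isfinite(values))
        if observed.size:
            noisy = observed[rng.random(observed.size) < 0.1]
            sd = values[observed].std() or 1.0
            table.iloc[noisy, loc] = values[noisy] + rng.normal(
                0.0, 3.0 * sd, size=noisy.size
            )
    return EdgeDataset(dataset.node_id, table, dataset.labels.copy())


@dataclass
class ScenarioManifest:
    cohort: CohortSpec
    column_missing_rates: dict[str, float]
    realized_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    outlier_rate: float = 0.03
    outlier_scale: float = 2.0
    corrupted_node: str = "node3"
    corruption_severity: float = 0.4


def standard_corrupted_scenario(
    seed: int,
    cohort: CohortSpec | None = None,
    *,
    corruption_severity: float = 0.4,
    outlier_rate: float = 0.03,
    missing_low: float = 0.05,
    missing_high: float = 0.30,
) -> tuple[list[EdgeDataset], list[EdgeDataset], ScenarioManifest]:
    """The study's standard 5-edge condition: MCAR column rates drawn from
    U(0.05, 0.30), mild outlier contamination everywhere, and one node
    (node3) corrupted past the completeness tolerance.

    Returns (corrupted edges, clean edges, manifest).
    """
    cohort = cohort or CohortSpec(seed=seed)
    if cohort.seed != seed:
        cohort = CohortSpec(
            n_edges=cohort.n_edges,
            rows_per_edge=cohort.rows_per_edge,
            n_features=cohort.n_features,
            class_proportions=cohort.class_proportions,
            class_separation=cohort.class_separation,
            seed=seed,
        )
    clean = generate_cohort(cohort)
    rate_rng = _rng(seed, "column-rates")
    columns = list(clean[0].table.columns)
    rates = {
        c: float(rate_rng.uniform(missing_low, missing_high)) for c in columns
    }
    manifest = ScenarioManifest(
        cohort=cohort,
        column_missing_rates=rates,
        outlier_rate=outlier_rate,
        corruption_severity=corruption_severity,
    )
    corrupted: list[EdgeDataset] = []
    spec = CorruptionSpec(
        missing_mechanism="MCAR",
        missing_rates=rates,
        outlier_rate=outlier_rate,
    )
    for edge in clean:
        damaged, realized = inject_missing(edge, spec, seed)
        manifest.realized_rates[edge.node_id] = realized
        damaged, _ = inject_outliers(
            damaged, outlier_rate, manifest.outlier_scale, seed
        )
        if edge.node_id == manifest.corrupted_node:
            damaged = corrupt_node(damaged, corruption_severity, seed)
        corrupted.append(damaged)
    return corrupted, clean, manifest
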