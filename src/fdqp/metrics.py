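"""Closed-form data-quality dimension metrics and per-column statistics.

The dimension metrics follow the standard closed forms used in the data
quality literature:

* completeness    ``1 - missing/total``
* timeliness      ``max(1 - currency/volatility, 0) ** s``
* correctness     ``1 / (d(w, w_m) + 1)`` for a domain distance ``d``
* uniqueness      distinct / total over non-missing values
* consistency     coefficient of variation (sample sd / |mean|), lower is
  more consistent; callers map it to [0, 1] via ``1 / (1 + CV)``

Column statistics (skewness, outlier fraction) use sample (n-1) moments
and Tukey IQR fences, the deterministic defaults for small per-edge
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimelinessParams",
    "CompletenessCounts",
    "CorrectnessInputs",
    "completeness_metric",
    "timeliness_metric",
    "correctness_metric",
    "uniqueness_metric",
    "consistency_cv",
    "consistency_score",
    "outlier_fraction",
    "skewness",
]


@dataclass(frozen=True)
class TimelinessParams:
    """Currency (age) and volatility (shelf life) share one time unit; the
    exponent ``s`` tunes sensitivity and defaults to 1 (expert-set)."""

    currency: float
    volatility: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.volatility <= 0:
            raise ValueError("volatility must be positive")
        if self.s <= 0:
            raise ValueError("exponent s must be positive")


@dataclass(frozen=True)
class CompletenessCounts:
    missing_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.missing_count <= self.total_count:
            raise ValueError("missing_count must lie in [0, total_count]")


@dataclass(frozen=True)
class CorrectnessInputs:
    distance: float
    stored_value: Any = None
    true_value: Any = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def completeness_metric(counts: CompletenessCounts) -> float:
    """Fraction of recorded cells: ``1 - missing/total``."""
    return 1.0 - counts.missing_count / counts.total_count


def timeliness_metric(params: TimelinessParams) -> float:
    """``max(1 - currency/volatility, 0) ** s``; 1 for fresh data, 0 past shelf life."""
    base = max(1.0 - params.currency / params.volatility, 0.0)
    return base**params.s


def correctness_metric(inputs: CorrectnessInputs) -> float:
    """``1/(d + 1)``: 1 iff the stored value matches reality, decaying with distance."""
    return 1.0 / (inputs.distance + 1.0)


def _dropna(column: Sequence[Any] | pd.Series | np.ndarray) -> pd.Series:
    return pd.Series(list(column) if not isinstance(column, pd.Series) else column).dropna()


def uniqueness_metric(column: Sequence[Any] | pd.Series) -> float:
    """Distinct non-missing values divided by non-missing count."""
    values = _dropna(column)
    if values.empty:
        raise ValueError("uniqueness is undefined for an all-missing column")
    return values.nunique() / len(values)


def consistency_cv(column: Sequence[float] | pd.Series) -> float:
    """Coefficient of variation: sample standard deviation over |mean|."""
    values = pd.to_numeric(_dropna(column))
    if len(values) < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    return float(values.std(ddof=1) / abs(mean))


def consistency_score(mean_cv: float) -> float:
    """Map a (mean) coefficient of variation to [0, 1], higher = more consistent."""
    if mean_cv < 0:
        raise ValueError("coefficient of variation cannot be negative")
    return 1.0 / (1.0 + mean_cv)


def outlier_fraction(
    column: Sequence[float] | pd.Series,
    method: str = "iqr",
    k: float = 1.5,
) -> float:
    """Fraction of non-missing values flagged as outliers.

    ``method="iqr"`` (default): outside the Tukey fences
    ``[Q1 - k*IQR, Q3 + k*IQR]`` with ``k=1.5``.
    ``method="zscore"``: ``|z| > k`` with ``k`` typically 3.
    """
    values = pd.to_numeric(_dropna(column), errors="raise").to_numpy(float)
    if method == "iqr":
        if len(values) < 4:
            raise ValueError("IQR outlier detection needs >= 4 non-missing values")
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        return float(np.mean((values < lo) | (values > hi)))
    if method == "zscore":
        if len(values) < 2:
            raise ValueError("z-score outlier detection needs >= 2 values")
        sd = values.std(ddof=1)
        if sd == 0:
            return 0.0
        z = (values - values.mean()) / sd
        return float(np.mean(np.abs(z) > k))
    raise ValueError(f"unknown outlier method {method!r}")


def skewness(column: Sequence[float] | pd.Series) -> float:
    """Adjusted Fisher-Pearson standardized third moment.

    ``g1 * sqrt(n(n-1))/(n-2)`` with ``g1 = m3 / m2^(3/2)``; the estimator
    pandas and spreadsheet software report.
    """
    values = pd.to_numeric(_dropna(column)).to_numpy(float)
    n = len(values)
    if n < 3:
        raise ValueError("skewness needs at least 3 non-missing values")
    mean = values.mean()
    m2 = np.mean((values - mean) ** 2)
    if m2 == 0:
        raise ValueError("skewness is undefined for zero variance")
    m3 = np.mean((values - mean) ** 3)
    g1 = m3 / m2**1.5
    return float(g1 * math.sqrt(n * (n - 1)) / (n - 2))
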