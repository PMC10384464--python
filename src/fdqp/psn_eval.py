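"""Patient-similarity evaluation: the federation loop's accuracy signal.

The similarity structure is a Gaussian kernel over z-scored features,
``S_ij = exp(-||z_i - z_j||^2 / (2 sigma^2))`` with the bandwidth defaulting
to the median pairwise distance.  Each patient is classified with the label
of their most similar *other* patient (leave-one-out 1-nearest-neighbour,
ties broken by lower row index), and per-edge accuracies are federated as a
row-count-weighted mean.  ``compare_pre_post`` is the before/after surface:
accuracy on the corrupted inputs versus the quality-enriched outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .local_profiler import EdgeDataset

__all__ = [
    "SimilarityMatrix",
    "FederatedScore",
    "similarity_matrix",
    "most_similar_prediction",
    "edge_accuracy",
    "federated_accuracy",
    "compare_pre_post",
]


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    node_id: str | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FederatedScore:
    per_edge_accuracy: list[float]
    weights: list[float]
    federated_accuracy: float


def similarity_matrix(
    table: pd.DataFrame, bandwidth: float | None = None, node_id: str | None = None
) -> SimilarityMatrix:
    """Gaussian-kernel similarity on z-scored features.

    Requires a complete (post-repair) numeric table with at least two rows;
    zero-variance columns carry no distance information and are dropped.
    """
    if table.isna().any().any():
        raise ValueError("similarity requires a complete table (no missing cells)")
    if len(table) < 2:
        raise ValueError("similarity needs at least 2 rows")
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    dist = pdist(Z)
    if bandwidth is None:
        positive = dist[dist > 0]
        bandwidth = float(np.median(positive)) if positive.size else 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    D2 = squareform(dist) ** 2
    S = np.exp(-D2 / (2.0 * bandwidth**2))
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, node_id=node_id)


def most_similar_prediction(S: SimilarityMatrix, labels: Sequence) -> pd.Series:
    """Label each patient with their most similar other patient's label.

    Self-similarity is excluded (leave-one-out); equal similarities resolve
    to the lower row index, making the prediction deterministic.
    """
    labels = pd.Series(list(labels)).reset_index(drop=True)
    n = S.n
    if len(labels) != n:
        raise ValueError("labels length must equal the matrix size")
    if n < 2:
        raise ValueError("need at least 2 patients")
    scores = S.values.copy()
    np.fill_diagonal(scores, -np.inf)
    nearest = scores.argmax(axis=1)  # argmax returns the first (lowest) index on ties
    return labels.iloc[nearest].reset_index(drop=True)


def edge_accuracy(dataset: EdgeDataset, bandwidth: float | None = None) -> float:
    """Leave-one-out most-similar-patient accuracy for one edge.

    Missing cells (only possible pre-repair) are filled with column means for
    the purpose of the distance computation; this is the naive baseline a node
    without quality profiling would use.
    """
    table = dataset.table
    if table.isna().any().any():
        table = table.fillna(table.mean(numeric_only=True))
        table = table.dropna(axis=1, how="any")  # all-missing columns
    S = similarity_matrix(table, bandwidth=bandwidth, node_id=dataset.node_id)
    predicted = most_similar_prediction(S, dataset.labels)
    actual = dataset.labels.reset_index(drop=True)
    return float((predicted == actual).mean())


def federated_accuracy(
    accuracies: Sequence[float], row_counts: Sequence[float]
) -> FederatedScore:
    """Row-count-weighted mean of per-edge accuracies."""
    if len(accuracies) == 0 or len(accuracies) != len(row_counts):
        raise ValueError("need equal-length, non-empty accuracy and count lists")
    if any(c <= 0 for c in row_counts):
        raise ValueError("row counts must be positive")
    weights = [float(c) for c in row_counts]
    fed = float(np.average(accuracies, weights=weights))
    return FederatedScore(
        per_edge_accuracy=[float(a) for a in accuracies],
        weights=weights,
        federated_accuracy=fed,
    )


@dataclass
class PrePostComparison:
    per_edge: list[dict] = field(default_factory=list)
    federated_before: float = float("nan")
    federated_after: float = float("nan")

    @property
    def federated_delta(self) -> float:
        return self.federated_after - self.federated_before


def compare_pre_post(
    edges_raw: Sequence[EdgeDataset],
    edges_enriched: Sequence[EdgeDataset],
) -> PrePostComparison:
    """Accuracy on corrupted inputs vs quality-enriched outputs.

    Edges are matched by node id; a node present only in the raw list (an
    eliminated node) still counts in the federated "before" score, which is
    exactly how a quality-unaware federation would have used it.
    """
    enriched_by_id = {e.node_id: e for e in edges_enriched}
    comparison = PrePostComparison()
    before_accs, before_n = [], []
    after_accs, after_n = [], []
    for raw in edges_raw:
        acc_raw = edge_accuracy(raw)
        before_accs.append(acc_raw)
        before_n.append(raw.n_rows)
        record = {"node_id": raw.node_id, "accuracy_before": acc_raw}
        enriched = enriched_by_id.get(raw.node_id)
        if enriched is not None:
            acc_post = edge_accuracy(enriched)
            record["accuracy_after"] = acc_post
            record["delta"] = acc_post - acc_raw
            after_accs.append(acc_post)
            after_n.append(enriched.n_rows)
        else:
            record["eliminated"] = True
        comparison.per_edge.append(record)
    comparison.federated_before = federated_accuracy(
        before_accs, before_n
    ).federated_accuracy
    if after_accs:
        comparison.federated_after = federated_accuracy(
            after_accs, after_n
        ).federated_accuracy
    return comparison
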