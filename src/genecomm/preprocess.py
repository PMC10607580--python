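"""Normalization and unsupervised sample-structure diagnostics.

Covers the two normalization steps applied to expression matrices (log2
transform and quantile normalization) and the unsupervised check used to
decide whether two nominal sample classes are distinguishable: within-sum-
of-squares and silhouette curves over k, k-means at the chosen k, and a
contingency comparison of clusters against the nominal classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionMatrix

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "QuantileNormalizer",
    "kmeans_cluster",
    "cluster_diagnostics",
    "contingency_agreement",
    "ClusterDiagnostics",
    "ContingencyResult",
]


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``.

    Raises ``ValueError`` naming the offending coordinates if any shifted
    value is non-positive.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    shifted = m.values + offset
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {m.values[i, j]!r} (offset {offset}) at gene "
            f"{m.gene_ids[i]!r}, sample {m.sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), np.log2(shifted), m.labels
    )


def _quantile_normalize_array(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a 2-D array.

    Every column is replaced by the rank-wise mean of the sorted columns
    (the reference distribution).  Ties within a column receive the average
    of the reference values over the tied rank span.
    """
    n_rows, n_cols = values.shape
    if n_cols < 2:
        raise ValueError(
            "quantile normalization needs at least 2 samples "
            "(no reference distribution otherwise)"
        )
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    ranks_grid = np.arange(1, n_rows + 1, dtype=float)
    for j in range(n_cols):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_grid, reference)
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples (columns) of an expression matrix.

    After normalization every sample shares the same value distribution:
    for tie-free columns the sorted values of every column are identical to
    the reference (mean of sorted columns), and the operation is idempotent.
    """
    return ExpressionMatrix(
        list(m.gene_ids),
        list(m.sample_ids),
        _quantile_normalize_array(m.values),
        m.labels,
    )


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style quantile normalization against a stored reference.

    ``fit`` learns the reference distribution (rank-wise mean of the sorted
    training rows); ``transform`` maps each row of X — X is oriented the
    sklearn way, samples in rows and genes in columns — onto that
    reference.  ``fit_transform`` on the training data therefore reproduces
    classical quantile normalization of the training matrix itself.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        # reference over the training samples: mean of per-sample sorted rows
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        n_ref = self.reference_.shape[0]
        out = np.empty_like(X, dtype=float)
        grid = np.linspace(1.0, n_ref, X.shape[1])
        for i in range(X.shape[0]):
            ranks = rankdata(X[i], method="average")
            # map ranks into the reference grid (handles n_features == n_ref
            # exactly; interpolates otherwise)
            out[i] = np.interp(ranks, np.arange(1, n_ref + 1), self.reference_) \
                if X.shape[1] == n_ref else np.interp(
                    (ranks - 1) / max(X.shape[1] - 1, 1) * (n_ref - 1) + 1,
                    np.arange(1, n_ref + 1),
                    self.reference_,
                )
        return out


def _sample_feature_matrix(
    m: ExpressionMatrix, top_variance_genes: int | None = None
) -> np.ndarray:
    """Samples x genes feature matrix for clustering, optionally restricted
    to the highest-variance genes."""
    X = m.values.T
    if top_variance_genes is not None and top_variance_genes < m.n_genes:
        order = np.argsort(m.values.var(axis=1))[::-1][:top_variance_genes]
        X = m.values[np.sort(order), :].T
    return X


def kmeans_cluster(
    m: ExpressionMatrix,
    k: int,
    n_starts: int = 25,
    seed: int = 0,
    top_variance_genes: int | None = None,
) -> dict[str, int]:
    """Best-of-``n_starts`` Lloyd k-means over samples (Euclidean, k-means++
    seeding).  Deterministic given ``seed``.  Returns sample id -> cluster.
    """
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({m.n_samples})")
    X = _sample_feature_matrix(m, top_variance_genes)
    km = KMeans(
        n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd"
    ).fit(X)
    return dict(zip(m.sample_ids, (int(c) for c in km.labels_)))


@dataclass
class ClusterDiagnostics:
    """WSS and silhouette curves over candidate k, plus the chosen k.

    ``chosen_k`` is the silhouette argmax; the WSS (elbow) curve is reported
    for inspection but not used for the automated choice.
    """

    k_values: list[int]
    wss: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int

    def to_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "wss": {str(k): v for k, v in self.wss.items()},
            "silhouette": {str(k): v for k, v in self.silhouette.items()},
            "chosen_k": self.chosen_k,
        }


def cluster_diagnostics(
    m: ExpressionMatrix,
    k_max: int = 6,
    n_starts: int = 25,
    seed: int = 0,
    top_variance_genes: int | None = None,
) -> ClusterDiagnostics:
    """WSS for k=1..k_max and silhouette for k=2..k_max over samples."""
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    X = _sample_feature_matrix(m, top_variance_genes)
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical: silhouette undefined")
    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    grand = X.mean(axis=0)
    wss[1] = float(((X - grand) ** 2).sum())
    for k in range(2, k_max + 1):
        km = KMeans(
            n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd"
        ).fit(X)
        wss[k] = float(km.inertia_)
        if k <= X.shape[0] - 1:  # silhouette undefined for k = n_samples
            sil[k] = float(silhouette_score(X, km.labels_))
    chosen = max(sil, key=lambda k: (sil[k], -k))
    return ClusterDiagnostics(
        k_values=list(range(1, k_max + 1)), wss=wss, silhouette=sil, chosen_k=chosen
    )


@dataclass
class ContingencyResult:
    """Class x cluster contingency table and the merged-class agreement.

    ``agreement_pct`` is the percentage of samples from the designated class
    union that fall in that union's single majority cluster (ties broken
    toward the lower cluster id).
    """

    table: pd.DataFrame
    agreement_pct: float
    majority_cluster: int


def contingency_agreement(
    labels: dict[str, str],
    clusters: dict[str, int],
    merge_classes: set[str],
) -> ContingencyResult:
    if set(labels) != set(clusters):
        raise ValueError("labels and clusters cover different sample sets")
    if not merge_classes:
        raise ValueError("merge_classes must not be empty")
    samples = sorted(labels)
    cls = pd.Series({s: labels[s] for s in samples}, name="class")
    clu = pd.Series({s: clusters[s] for s in samples}, name="cluster")
    table = pd.crosstab(cls, clu)
    merged = [s for s in samples if labels[s] in merge_classes]
    if not merged:
        raise ValueError(f"no samples in classes {sorted(merge_classes)}")
    counts: dict[int, int] = {}
    for s in merged:
        counts[clusters[s]] = counts.get(clusters[s], 0) + 1
    majority = min(
        counts, key=lambda c: (-counts[c], c)
    )  # max count, tie -> lower cluster id
    pct = 100.0 * counts[majority] / len(merged)
    return ContingencyResult(table=table, agreement_pct=pct, majority_cluster=majority)
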