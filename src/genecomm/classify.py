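"""Random-forest classification of communities with repeated cross-validation.

Each gene community yields one classifier: a bootstrap ensemble of M CART
trees (default M=300) considering all features at every split (s = |S|),
evaluated by stratified k-fold cross-validation repeated many times.  Four
metrics are reported: accuracy, AUC (positive/negative pair counting with
half credit for ties), F1 of the positive (tumor) class, and cross-entropy
log loss on the natural-log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "CVConfig",
    "MetricSet",
    "CVReport",
    "train_rf",
    "compute_metrics",
    "repeated_cv",
    "rank_communities",
    "external_validate",
]

_EPS = 1e-15


@dataclass
class RFConfig:
    """Random forest settings: M trees, mtry policy, seed.

    ``mtry="all_features"`` considers every input feature at each split
    (bagged trees, s = |S|); ``"sqrt"`` is the common forest default.
    """

    n_trees: int = 300
    mtry: str = "all_features"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry not in ("all_features", "sqrt"):
            raise ValueError(f"unknown mtry policy {self.mtry!r}")


@dataclass
class CVConfig:
    """Repeated stratified k-fold settings (5 folds x 100 repeats default)."""

    k_folds: int = 5
    repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class MetricSet:
    """Accuracy / AUC / F1 in percent, log loss in nats."""

    accuracy: float
    auc: float
    f1: float
    logloss: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "f1": self.f1,
            "logloss": self.logloss,
        }


@dataclass
class CVReport:
    """Per-repeat metric sets (held-out predictions pooled per repeat)."""

    rounds: list[MetricSet] = field(default_factory=list)

    def mean(self) -> MetricSet:
        return MetricSet(
            accuracy=float(np.mean([r.accuracy for r in self.rounds])),
            auc=float(np.mean([r.auc for r in self.rounds])),
            f1=float(np.mean([r.f1 for r in self.rounds])),
            logloss=float(np.mean([r.logloss for r in self.rounds])),
        )

    def sd(self) -> MetricSet:
        return MetricSet(
            accuracy=float(np.std([r.accuracy for r in self.rounds], ddof=1))
            if len(self.rounds) > 1
            else 0.0,
            auc=float(np.std([r.auc for r in self.rounds], ddof=1))
            if len(self.rounds) > 1
            else 0.0,
            f1=float(np.std([r.f1 for r in self.rounds], ddof=1))
            if len(self.rounds) > 1
            else 0.0,
            logloss=float(np.std([r.logloss for r in self.rounds], ddof=1))
            if len(self.rounds) > 1
            else 0.0,
        )

    def to_dict(self) -> dict:
        return {
            "rounds": [r.to_dict() for r in self.rounds],
            "mean": self.mean().to_dict(),
            "sd": self.sd().to_dict(),
        }

    def format_row(self) -> dict[str, str]:
        m, s = self.mean(), self.sd()
        return {
            "Accuracy": f"{m.accuracy:.2f} ± {s.accuracy:.2f}",
            "AUC": f"{m.auc:.2f} ± {s.auc:.2f}",
            "F1": f"{m.f1:.2f} ± {s.f1:.2f}",
            "LogLoss": f"{m.logloss:.2f} ± {s.logloss:.2f}",
        }


def train_rf(
    X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None
) -> RandomForestClassifier:
    """Fit the M-tree bootstrap CART ensemble; deterministic given the seed."""
    cfg = cfg or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).shape[0] < 2:
        raise ValueError("labels contain a single class")
    max_features = None if cfg.mtry == "all_features" else "sqrt"
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    return rf.fit(X, y)


def pairwise_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """P(score_pos > score_neg) with half credit for ties, in [0, 1].

    Computed through the Mann-Whitney rank identity, which equals explicit
    pair counting exactly (average ranks give the half-credit tie rule).
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(y_prob, method="average")
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """Accuracy, pair-counting AUC, F1 of the positive class and log loss.

    A sample is called positive when its probability strictly exceeds the
    threshold.  Probabilities are clipped to [1e-15, 1-1e-15] for log loss.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    y_pred = (y_prob > threshold).astype(int)
    accuracy = 100.0 * float((y_pred == y_true).mean())
    auc = 100.0 * pairwise_auc(y_true, y_prob)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    if tp == 0:
        f1 = 0.0
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 100.0 * 2 * precision * recall / (precision + recall)
    p = np.clip(y_prob, _EPS, 1.0 - _EPS)
    logloss = float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))
    return MetricSet(accuracy=accuracy, auc=auc, f1=f1, logloss=logloss)


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    rf: RFConfig | None = None,
    cv: CVConfig | None = None,
) -> CVReport:
    """Repeated (stratified) k-fold cross-validation over samples.

    Every repeat draws a fresh fold split; held-out probabilities of the
    repeat are pooled into one metric set, and the report aggregates
    mean +/- sd over repeats.  Folds always split samples, never features.
    """
    rf = rf or RFConfig()
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if cv.stratified and counts[counts > 0].min() < cv.k_folds:
        raise ValueError(
            f"stratified {cv.k_folds}-fold CV infeasible: smallest class has "
            f"{counts[counts > 0].min()} samples"
        )
    report = CVReport()
    rng = np.random.default_rng(cv.seed)
    for rep in range(cv.repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        splitter = (
            StratifiedKFold(cv.k_folds, shuffle=True, random_state=split_seed)
            if cv.stratified
            else KFold(cv.k_folds, shuffle=True, random_state=split_seed)
        )
        prob = np.full(y.shape[0], np.nan)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            fold_cfg = RFConfig(
                n_trees=rf.n_trees,
                mtry=rf.mtry,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            model = train_rf(X[train_idx], y[train_idx], fold_cfg)
            pos_col = list(model.classes_).index(1)
            prob[test_idx] = model.predict_proba(X[test_idx])[:, pos_col]
        assert not np.isnan(prob).any(), "held-out predictions must cover all samples"
        report.rounds.append(compute_metrics(y, prob))
    return report


def rank_communities(
    reports: dict, accuracy_cutoff: float = 90.0
) -> list[tuple[object, float]]:
    """Communities whose mean CV accuracy exceeds the cutoff, best first."""
    selected = [
        (comm, rep.mean().accuracy)
        for comm, rep in reports.items()
        if rep.mean().accuracy > accuracy_cutoff
    ]
    selected.sort(key=lambda t: (-t[1], str(t[0])))
    return selected


def external_validate(
    model: RandomForestClassifier,
    genes: list[str],
    test_matrix: ExpressionMatrix,
    train_means: dict[str, float],
    positive_class: str = "tumor",
) -> MetricSet:
    """Single-shot evaluation of a trained community classifier on an
    independent dataset.

    Features are matched by gene id; genes absent from the test matrix are
    imputed at their training-set mean (with a logged count).  Returns one
    point estimate per metric (no cross-validation).
    """
    index = {g: i for i, g in enumerate(test_matrix.gene_ids)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if not present:
        raise ValueError("no overlap between model genes and test matrix")
    if missing:
        logger.warning(
            "imputing %d/%d genes absent from the test matrix at training means",
            len(missing),
            len(genes),
        )
    n_samples = test_matrix.n_samples
    X = np.empty((n_samples, len(genes)))
    for j, g in enumerate(genes):
        if g in index:
            X[:, j] = test_matrix.values[index[g], :]
        else:
            X[:, j] = train_means[g]
    y = (test_matrix.label_array() == positive_class).astype(int)
    pos_col = list(model.classes_).index(1)
    prob = model.predict_proba(X)[:, pos_col]
    return compute_metrics(y, prob)
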