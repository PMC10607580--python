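"""Boruta all-relevant feature selection and the selection/classification split.

Boruta pits every feature against "shadow" copies of the feature matrix —
columns permuted across samples so that any association with the class
label is destroyed while the marginal distribution is preserved.  A feature
scores a *hit* in an iteration when its random-forest importance exceeds
the best shadow importance; cumulative hit counts are tested against
Binomial(n_iterations, 1/2) to confirm (upper tail) or reject (lower tail)
features at a Bonferroni-corrected level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BorutaConfig",
    "BorutaResult",
    "SplitConfig",
    "make_shadow_features",
    "boruta_select",
    "split_selection_classification",
    "BorutaSelector",
]


@dataclass
class BorutaConfig:
    """Boruta settings.

    ``rf_trees`` sizes the internal random forest (which uses sqrt-mtry, the
    conventional forest default for this wrapper); ``alpha`` is the
    per-test level before correction; ``importance`` is ``"impurity"``
    (fast, default) or ``"permutation"``.
    """

    max_iterations: int = 100
    alpha: float = 0.05
    correction: str = "bonferroni"  # or "none"
    rf_trees: int = 300
    importance: str = "impurity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance measure {self.importance!r}")


@dataclass
class BorutaResult:
    """Per-feature outcome of a Boruta run.

    ``statuses`` partitions the features into confirmed / rejected /
    tentative; ``hit_counts`` are cumulative shadow-beating counts;
    ``importance_history`` holds per-iteration (feature importances, max
    shadow importance) for the features still in play.
    """

    statuses: list[str]
    hit_counts: np.ndarray
    n_iterations_run: int
    importance_history: list[dict] = field(default_factory=list)

    def confirmed_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.statuses) if s == "confirmed"]

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        names = feature_names or [f"f{i}" for i in range(len(self.statuses))]
        return {
            "n_iterations_run": self.n_iterations_run,
            "features": {
                name: {"status": s, "hits": int(h)}
                for name, s, h in zip(names, self.statuses, self.hit_counts)
            },
        }


def make_shadow_features(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """One shadow per feature: the column permuted across samples,
    independently per feature.  Each shadow is multiset-equal to its source
    column."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    rng = np.random.default_rng(seed)
    shadows = np.empty_like(X)
    for j in range(X.shape[1]):
        shadows[:, j] = rng.permutation(X[:, j])
    return shadows


def _importances(
    rf: RandomForestClassifier,
    X_ext: np.ndarray,
    y: np.ndarray,
    cfg: BorutaConfig,
    rng_seed: int,
) -> np.ndarray:
    if cfg.importance == "impurity":
        return rf.feature_importances_
    res = permutation_importance(
        rf, X_ext, y, n_repeats=5, random_state=rng_seed, n_jobs=1
    )
    return res.importances_mean


def boruta_select(
    X: np.ndarray, y: np.ndarray, cfg: BorutaConfig | None = None
) -> BorutaResult:
    """Run Boruta on a samples x features matrix with binary labels.

    Each iteration regenerates fresh shadows, fits a random forest on the
    extended matrix, and scores hits against the best shadow importance.
    After every iteration, features whose hit count is in the upper
    (resp. lower) tail of Binomial(t, 1/2) at the corrected level are
    confirmed (resp. rejected and removed from the pool).  Stops when no
    tentative features remain or ``max_iterations`` is reached.
    """
    cfg = cfg or BorutaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("labels contain a single class")
    n_features = X.shape[1]
    statuses = ["tentative"] * n_features
    hits = np.zeros(n_features, dtype=int)
    active = list(range(n_features))
    history: list[dict] = []
    rng = np.random.default_rng(cfg.seed)

    t = 0
    for t in range(1, cfg.max_iterations + 1):
        Xa = X[:, active]
        shadow_seed = int(rng.integers(0, 2**31 - 1))
        shadows = make_shadow_features(Xa, seed=shadow_seed)
        X_ext = np.hstack([Xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        ).fit(X_ext, y)
        imp = _importances(rf, X_ext, y, cfg, shadow_seed)
        feat_imp = imp[: len(active)]
        shadow_max = float(imp[len(active):].max())
        for pos, f in enumerate(active):
            if feat_imp[pos] > shadow_max:
                hits[f] += 1
        history.append(
            {
                "iteration": t,
                "features": {int(f): float(feat_imp[pos]) for pos, f in enumerate(active)},
                "shadow_max": shadow_max,
            }
        )
        tentative = [f for f in active if statuses[f] == "tentative"]
        n_tests = max(len(tentative), 1)
        level = cfg.alpha / n_tests if cfg.correction == "bonferroni" else cfg.alpha
        newly_rejected: list[int] = []
        for f in tentative:
            p_up = float(binom.sf(hits[f] - 1, t, 0.5))  # P(X >= hits)
            p_down = float(binom.cdf(hits[f], t, 0.5))  # P(X <= hits)
            if p_up < level:
                statuses[f] = "confirmed"
            elif p_down < level:
                statuses[f] = "rejected"
                newly_rejected.append(f)
        active = [f for f in active if f not in newly_rejected]
        if not any(s == "tentative" for s in statuses):
            break
        if not active:
            break
    return BorutaResult(
        statuses=statuses,
        hit_counts=hits,
        n_iterations_run=t,
        importance_history=history,
    )


@dataclass
class SplitConfig:
    """Selection/classification sample split (40% / 60% by default)."""

    selection_fraction: float = 0.40
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.selection_fraction < 1.0):
            raise ValueError("selection_fraction must lie in (0, 1)")


def split_selection_classification(
    sample_ids: list[str],
    labels: dict[str, str],
    cfg: SplitConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Split samples into a feature-selection set and a classification set.

    The selection set holds ``round(selection_fraction * n)`` samples,
    stratified by class when requested (per-class counts proportional,
    largest-remainder rounding).  Disjoint, union = all samples,
    deterministic given the seed.
    """
    cfg = cfg or SplitConfig()
    classes = sorted({labels[s] for s in sample_ids})
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    by_class = {c: [s for s in sample_ids if labels[s] == c] for c in classes}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    n = len(sample_ids)
    n_sel = int(round(cfg.selection_fraction * n))
    n_sel = min(max(n_sel, 1), n - 1)
    rng = np.random.default_rng(cfg.seed)
    selection: list[str] = []
    if cfg.stratified:
        exact = {c: cfg.selection_fraction * len(by_class[c]) for c in classes}
        take = {c: int(np.floor(exact[c])) for c in classes}
        remainder = sorted(
            classes, key=lambda c: (-(exact[c] - take[c]), c)
        )
        i = 0
        while sum(take.values()) < n_sel:
            take[remainder[i % len(classes)]] += 1
            i += 1
        while sum(take.values()) > n_sel:
            take[remainder[-1 - (i % len(classes))]] -= 1
            i += 1
        for c in classes:
            members = list(by_class[c])
            picked = rng.choice(len(members), size=take[c], replace=False)
            selection.extend(members[k] for k in sorted(picked))
    else:
        picked = rng.choice(n, size=n_sel, replace=False)
        selection = [sample_ids[k] for k in sorted(picked)]
    selection_set = set(selection)
    classification = [s for s in sample_ids if s not in selection_set]
    return selection, classification


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Sklearn-style Boruta feature selector.

    ``fit(X, y)`` runs the shadow-competition procedure; ``transform``
    keeps confirmed features (optionally also tentative ones via
    ``keep_tentative=True``).
    """

    def __init__(
        self,
        max_iterations: int = 100,
        alpha: float = 0.05,
        correction: str = "bonferroni",
        rf_trees: int = 300,
        importance: str = "impurity",
        keep_tentative: bool = False,
        random_state: int = 0,
    ) -> None:
        self.max_iterations = max_iterations
        self.alpha = alpha
        self.correction = correction
        self.rf_trees = rf_trees
        self.importance = importance
        self.keep_tentative = keep_tentative
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cfg = BorutaConfig(
            max_iterations=self.max_iterations,
            alpha=self.alpha,
            correction=self.correction,
            rf_trees=self.rf_trees,
            importance=self.importance,
            seed=self.random_state,
        )
        self.result_ = boruta_select(X, y, cfg)
        statuses = np.asarray(self.result_.statuses)
        self.support_ = statuses == "confirmed"
        self.support_weak_ = statuses == "tentative"
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        if self.keep_tentative:
            return self.support_ | self.support_weak_
        return self.support_
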