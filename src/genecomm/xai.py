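"""Shapley-value attribution for community classifiers.

The Shapley value of feature j for an instance x is the factorially
weighted average, over feature subsets F not containing j, of the marginal
change in the model's value when j is added:

    SHAP_j(x) = sum_{F subset S\\{j}} |F|! (|S|-|F|-1)! / |S|!  [v(F+j) - v(F)]

The value v(F) of a coalition is the interventional expectation: features
in F take the instance's values, features outside F are replaced by rows of
a fixed background sample, and the model output (positive-class
probability) is averaged over the background.  Two estimators are provided:
exact subset enumeration for small feature sets (|S| <= 15) and a
Monte-Carlo permutation estimator that converges to the exact values and
preserves local accuracy (base value + sum of attributions = model output)
at any number of permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapExplanation",
    "ShapSummary",
    "exact_shap",
    "approx_shap",
    "shap_summary",
    "plot_shap_summary",
]

ENUMERATION_BOUND = 15


@dataclass
class ShapExplanation:
    """SHAP values for a set of explained samples.

    ``base_value`` is the expected model output over the background;
    local accuracy holds per sample: base + sum_j shap[sample, j] equals
    the model output at that sample (up to Monte-Carlo noise of the
    estimator, exactly in expectation).
    """

    base_value: float
    shap_values: np.ndarray  # (n_samples, n_features)
    feature_values: np.ndarray  # (n_samples, n_features)

    def local_accuracy_gap(self, outputs: np.ndarray) -> np.ndarray:
        return np.abs(self.base_value + self.shap_values.sum(axis=1) - outputs)


def _as_value_function(model_or_fn):
    """Accept a fitted classifier (positive-class probability) or a raw
    callable mapping (n, d) arrays to outputs."""
    if hasattr(model_or_fn, "predict_proba"):
        pos_col = list(model_or_fn.classes_).index(model_or_fn.classes_.max())

        def f(rows: np.ndarray) -> np.ndarray:
            return model_or_fn.predict_proba(rows)[:, pos_col]

        return f
    return model_or_fn


def exact_shap(
    predict,
    x: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Exact Shapley values by subset enumeration.

    ``predict`` maps (n, d) arrays to scalar outputs; ``x`` is one instance
    of d features; ``background`` is the reference sample for absent
    features.  Enumerates all 2^d coalitions (d <= 15) and applies the
    factorial weights directly.
    """
    f = _as_value_function(predict)
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.shape[0]
    if d > ENUMERATION_BOUND:
        raise ValueError(
            f"{d} features exceed the enumeration bound {ENUMERATION_BOUND}; "
            "use approx_shap"
        )
    n_bg = background.shape[0]
    n_masks = 1 << d
    # value of every coalition, computed in one batched prediction
    rows = np.empty((n_masks * n_bg, d))
    for mask in range(n_masks):
        block = background.copy()
        for j in range(d):
            if mask >> j & 1:
                block[:, j] = x[j]
        rows[mask * n_bg : (mask + 1) * n_bg] = block
    values = np.asarray(f(rows), dtype=float).reshape(n_masks, n_bg).mean(axis=1)

    fact = [math.factorial(k) for k in range(d + 1)]
    weights = [fact[k] * fact[d - k - 1] / fact[d] for k in range(d)]
    phi = np.zeros(d)
    for j in range(d):
        bit = 1 << j
        for mask in range(n_masks):
            if mask & bit:
                continue
            k = bin(mask).count("1")
            phi[j] += weights[k] * (values[mask | bit] - values[mask])
    return phi


def approx_shap(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    batch_rows: int = 65536,
) -> ShapExplanation:
    """Monte-Carlo permutation estimate of the Shapley values.

    For each sampled feature ordering the features of the instance are
    switched on one by one (over the full background), and the marginal
    output changes are credited to the switched feature.  Contributions
    telescope, so local accuracy holds exactly for every sample at any
    ``n_permutations``; as permutations grow the estimate converges to
    :func:`exact_shap`.  Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    f = _as_value_function(model)
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    n_explain, d = X_explain.shape
    n_bg = background.shape[0]
    base = float(np.mean(np.asarray(f(background), dtype=float)))
    rng = np.random.default_rng(seed)
    shap_values = np.zeros((n_explain, d))

    for s in range(n_explain):
        x = X_explain[s]
        perms = [rng.permutation(d) for _ in range(n_permutations)]
        # rows for all prefixes of all permutations, evaluated in batches
        phi = np.zeros(d)
        pending_rows: list[np.ndarray] = []
        pending_meta: list[np.ndarray] = []  # permutation index per block
        for perm in perms:
            block = np.repeat(background[None, :, :], d + 1, axis=0)
            # block[k] = background with features perm[:k] set to x
            for k in range(1, d + 1):
                block[k] = block[k - 1]
                block[k, :, perm[k - 1]] = x[perm[k - 1]]
            pending_rows.append(block.reshape(-1, d))
            pending_meta.append(perm)
            if sum(b.shape[0] for b in pending_rows) >= batch_rows:
                _flush(f, pending_rows, pending_meta, n_bg, d, phi)
        _flush(f, pending_rows, pending_meta, n_bg, d, phi)
        shap_values[s] = phi / n_permutations
    return ShapExplanation(
        base_value=base, shap_values=shap_values, feature_values=X_explain
    )


def _flush(f, pending_rows, pending_meta, n_bg, d, phi) -> None:
    if not pending_rows:
        return
    rows = np.vstack(pending_rows)
    out = np.asarray(f(rows), dtype=float).reshape(len(pending_meta), d + 1, n_bg)
    means = out.mean(axis=2)  # (n_perms_in_batch, d+1)
    for p_idx, perm in enumerate(pending_meta):
        deltas = np.diff(means[p_idx])
        for k, j in enumerate(perm):
            phi[j] += deltas[k]
    pending_rows.clear()
    pending_meta.clear()


@dataclass
class ShapSummary:
    """Global summary: features ranked by mean |SHAP|, with a direction
    score (sign of the correlation between feature value and SHAP value;
    positive means higher expression pushes toward the positive class)."""

    ranking: list[int]  # feature indices, most important first
    mean_abs_shap: np.ndarray
    direction: np.ndarray  # in {-1, 0, +1}
    feature_names: list[str] | None = None

    def to_dict(self) -> dict:
        names = self.feature_names or [f"f{i}" for i in range(len(self.mean_abs_shap))]
        return {
            "ranking": [
                {
                    "feature": names[i],
                    "mean_abs_shap": float(self.mean_abs_shap[i]),
                    "direction": int(self.direction[i]),
                }
                for i in self.ranking
            ]
        }


def shap_summary(
    exp: ShapExplanation,
    top_k: int = 20,
    feature_names: list[str] | None = None,
) -> ShapSummary:
    """Rank features by mean |SHAP| and score their direction of effect."""
    sv = exp.shap_values
    if sv.shape[0] < 1:
        raise ValueError("at least one explained sample required")
    mean_abs = np.abs(sv).mean(axis=0)
    d = sv.shape[1]
    direction = np.zeros(d, dtype=int)
    for j in range(d):
        fv = exp.feature_values[:, j]
        if np.std(fv) == 0 or np.std(sv[:, j]) == 0:
            direction[j] = 0
        else:
            r = np.corrcoef(fv, sv[:, j])[0, 1]
            direction[j] = int(np.sign(r)) if not np.isnan(r) else 0
    order = np.argsort(-mean_abs, kind="stable")[: min(top_k, d)]
    return ShapSummary(
        ranking=[int(i) for i in order],
        mean_abs_shap=mean_abs,
        direction=direction,
        feature_names=feature_names,
    )


def plot_shap_summary(
    exp: ShapExplanation,
    feature_names: list[str],
    path,
    top_k: int = 20,
) -> None:
    """Beeswarm-style summary: one row per top feature, points are samples,
    x = SHAP value, color = feature value (red high, blue low)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = shap_summary(exp, top_k=top_k, feature_names=feature_names)
    order = summary.ranking
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(order) + 1.5))
    rng = np.random.default_rng(0)
    for row, j in enumerate(reversed(order)):
        x = exp.shap_values[:, j]
        fv = exp.feature_values[:, j]
        lo, hi = fv.min(), fv.max()
        c = (fv - lo) / (hi - lo) if hi > lo else np.full_like(fv, 0.5)
        jitter = rng.uniform(-0.25, 0.25, size=x.shape[0])
        ax.scatter(x, row + jitter, c=c, cmap="coolwarm", s=12, alpha=0.8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([feature_names[j] for j in reversed(order)])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("SHAP value (impact on model output)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
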