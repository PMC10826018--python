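"""Shapley-value explanations of fitted risk classifiers.

The value function is the interventional (background-substitution)
expectation: v(S) is the mean model score over background rows with
the coalition's features replaced by the explained instance's values.
Two estimators are provided:

* :func:`exact_shapley` — the classic sum over all 2^m coalitions,
  exact for the given value function, feasible for m <= 12.  It serves
  as the oracle for the sampling estimator and makes the Shapley axioms
  (efficiency, symmetry, null player) directly testable.
* :func:`shap_values` — permutation sampling for the full feature set.
  Each sampled permutation contributes a telescoping walk from a
  background row to the instance, so per-instance local accuracy
  (base value + sum of attributions = model score) holds exactly when
  background rows are cycled uniformly, which this implementation does.

:func:`summarize` ranks features by mean absolute attribution, the
ordering a SHAP summary (beeswarm) plot displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

ScoreFn = Callable[[np.ndarray], np.ndarray]


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, float)
    return x[None, :] if x.ndim == 1 else x


def exact_shapley(
    score_fn: ScoreFn,
    instance: np.ndarray,
    background: np.ndarray,
    max_features: int = 12,
) -> np.ndarray:
    """Exact Shapley attributions of ``score_fn`` at one instance.

    Enumerates all coalitions; refuses more than ``max_features``
    features (the cost is 2^m model calls on the background).
    """
    instance = np.asarray(instance, float).ravel()
    background = _as_matrix(background)
    m = len(instance)
    if m > max_features:
        raise ValueError(
            f"exact Shapley limited to {max_features} features, got {m}"
        )
    if len(background) == 0:
        raise ValueError("background must be non-empty")

    # v(S) for every coalition, batched over the background
    n_coal = 2**m
    values = np.empty(n_coal)
    for code in range(n_coal):
        rows = background.copy()
        for j in range(m):
            if (code >> j) & 1:
                rows[:, j] = instance[j]
        values[code] = float(np.mean(score_fn(rows)))

    fact = [math.factorial(k) for k in range(m + 1)]
    phi = np.zeros(m)
    for code in range(n_coal):
        size = bin(code).count("1")
        w = fact[size] * fact[m - size - 1] / fact[m]
        for j in range(m):
            if not (code >> j) & 1:
                phi[j] += w * (values[code | (1 << j)] - values[code])
    return phi


@dataclass
class ShapSummary:
    """Per-instance, per-feature attributions with their base value."""

    attributions: np.ndarray  # (n_instances, n_features)
    base_value: float
    feature_names: list[str]
    scores: np.ndarray  # model score per explained instance

    @property
    def mean_abs(self) -> np.ndarray:
        return np.mean(np.abs(self.attributions), axis=0)

    def local_accuracy_error(self) -> np.ndarray:
        """|base + sum(attributions) - score| per instance."""
        return np.abs(self.base_value + self.attributions.sum(axis=1) - self.scores)


def shap_values(
    score_fn: ScoreFn,
    background: np.ndarray,
    explain_set: np.ndarray,
    feature_names: Sequence[str] | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> ShapSummary:
    """Permutation-sampling Shapley attributions for every explained row.

    ``n_permutations`` is rounded up to a multiple of the background size
    so each background row anchors the same number of telescoping walks,
    making local accuracy exact rather than approximate.
    """
    background = _as_matrix(background)
    explain_set = _as_matrix(explain_set)
    n_bg, m = background.shape
    if explain_set.shape[1] != m:
        raise ValueError("explain_set and background widths differ")
    if len(explain_set) == 0:
        raise ValueError("explain_set must be non-empty")
    rng = np.random.default_rng(seed)
    reps = max(1, math.ceil(n_permutations / n_bg))
    bg_order = np.tile(np.arange(n_bg), reps)  # uniform background cycling
    n_perm = len(bg_order)

    base_value = float(np.mean(score_fn(background)))
    scores = np.asarray(score_fn(explain_set), float).ravel()

    attributions = np.zeros((len(explain_set), m))
    for i, x in enumerate(explain_set):
        phi = np.zeros(m)
        for b_idx in bg_order:
            perm = rng.permutation(m)
            # telescoping walk: row k has the first k permuted features
            # replaced by the instance's values
            rows = np.tile(background[b_idx], (m + 1, 1))
            for k, j in enumerate(perm):
                rows[k + 1 :, j] = x[j]
            vals = np.asarray(score_fn(rows), float)
            phi[perm] += np.diff(vals)
        attributions[i] = phi / n_perm

    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(m)]
    )
    return ShapSummary(
        attributions=attributions,
        base_value=base_value,
        feature_names=names,
        scores=scores,
    )


def explain_model(
    model,
    background: np.ndarray,
    explain_set: np.ndarray,
    feature_names: Sequence[str] | None = None,
    max_background: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
) -> ShapSummary:
    """Explain a fitted classifier's positive-class probability.

    The background is capped at ``max_background`` rows by seeded
    subsampling (it is typically the training split).
    """
    background = _as_matrix(background)
    if len(background) > max_background:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(background), size=max_background, replace=False)
        background = background[keep]

    def score(rows: np.ndarray) -> np.ndarray:
        return model.predict_proba(rows)[:, 1]

    return shap_values(
        score,
        background,
        explain_set,
        feature_names=feature_names,
        n_permutations=n_permutations,
        seed=seed,
    )


def summarize(summary: ShapSummary, top_k: int | None = None) -> pd.DataFrame:
    """Features ranked by descending mean |attribution|; ties break by name."""
    if summary.attributions.size == 0:
        raise ValueError("summary is empty")
    mean_abs = summary.mean_abs
    order = sorted(
        range(len(summary.feature_names)),
        key=lambda j: (-mean_abs[j], summary.feature_names[j]),
    )
    if top_k is not None:
        order = order[:top_k]
    return pd.DataFrame(
        {
            "feature": [summary.feature_names[j] for j in order],
            "mean_abs_attribution": [float(mean_abs[j]) for j in order],
        }
    )
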