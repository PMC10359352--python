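"""Feature attribution for the trained surrogate.

Two complementary views of which process factor drives predicted alcohol
content:

* **Permutation importance (mean decrease accuracy).**  The increase in the
  model's mean squared error when one feature column is shuffled; a feature
  the model ignores scores exactly zero.  Repeated shufflings give a mean ±
  SD weight per feature.
* **Exact Shapley values.**  With only three predictors all 2³ coalitions
  are enumerated; an absent feature is integrated out by averaging the
  model's prediction over a background sample (the marginal/interventional
  expectation).  The attributions satisfy local accuracy exactly: base
  value + sum of attributions = model prediction for every sample.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from fermgan.table import PREDICTOR_COLUMNS, FeatureTable

__all__ = [
    "ImportanceResult",
    "ShapleyMatrix",
    "permutation_importance",
    "shapley_values",
    "importance_summary",
]

PredictFn = Callable[[np.ndarray], np.ndarray]


def _as_predict_fn(model) -> PredictFn:
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


@dataclass
class ImportanceResult:
    """Per-feature permutation weights (MSE increase) with repeat SDs."""

    feature_names: tuple[str, ...]
    weights: np.ndarray  # mean over repeats
    weights_sd: np.ndarray
    metric: str
    n_repeats: int
    seed: int

    def ranking(self) -> list[str]:
        order = np.argsort(-self.weights)
        return [self.feature_names[i] for i in order]

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "weights": self.weights.tolist(),
            "weights_sd": self.weights_sd.tolist(),
            "metric": self.metric,
            "n_repeats": self.n_repeats,
            "ranking": self.ranking(),
        }

    def summary(self) -> str:
        lines = ["Permutation importance (mean decrease accuracy, MSE)"]
        for name, w, s in sorted(
            zip(self.feature_names, self.weights, self.weights_sd), key=lambda t: -t[1]
        ):
            lines.append(f"  {name:<12s} {w:8.4f} ± {s:.4f}")
        return "\n".join(lines)


@dataclass
class ShapleyMatrix:
    """Exact per-sample Shapley attributions (°P) and the base value."""

    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    X: np.ndarray  # the explained samples (raw units)

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean_abs())
        return [self.feature_names[i] for i in order]

    def to_frame(self, scaled_X: np.ndarray | None = None) -> pd.DataFrame:
        """Per-sample export for beeswarm-style plots (raw and optionally scaled values)."""
        frames = {}
        for j, name in enumerate(self.feature_names):
            frames[f"phi_{name}"] = self.values[:, j]
            frames[f"value_{name}"] = self.X[:, j]
            if scaled_X is not None:
                frames[f"scaled_value_{name}"] = scaled_X[:, j]
        df = pd.DataFrame(frames)
        df["base_value"] = self.base_value
        return df


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] = PREDICTOR_COLUMNS,
) -> ImportanceResult:
    """Mean decrease accuracy: MSE(permuted) - MSE(intact), per feature.

    Shuffles are drawn under ``seed``; the same model and data always yield
    the same result.
    """
    predict = _as_predict_fn(model)
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] < 2:
        raise ValueError("permutation importance needs at least 2 rows")
    rng = np.random.default_rng(seed)
    baseline = float(np.mean((predict(X).ravel() - y) ** 2))
    deltas = np.empty((n_repeats, X.shape[1]))
    for r in range(n_repeats):
        for j in range(X.shape[1]):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            deltas[r, j] = float(np.mean((predict(Xp).ravel() - y) ** 2)) - baseline
    return ImportanceResult(
        tuple(feature_names),
        deltas.mean(axis=0),
        deltas.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(X.shape[1]),
        "mse",
        n_repeats,
        seed,
    )


def shapley_values(
    model,
    X: np.ndarray | FeatureTable,
    background: np.ndarray | FeatureTable,
    feature_names: Sequence[str] = PREDICTOR_COLUMNS,
) -> ShapleyMatrix:
    """Exact Shapley attribution by full coalition enumeration.

    ``v(S)`` is the mean prediction with the features in S taken from the
    explained sample and the rest from each background row in turn.  The
    classic weights |S|! (p-|S|-1)! / p! combine the marginal contributions.
    """
    predict = _as_predict_fn(model)
    if isinstance(X, FeatureTable):
        X = X.predictors
    if isinstance(background, FeatureTable):
        background = background.predictors
    X = np.atleast_2d(np.asarray(X, float))
    B = np.atleast_2d(np.asarray(background, float))
    if B.shape[0] == 0:
        raise ValueError("background must be non-empty")
    n, p = X.shape
    m = B.shape[0]

    # value of every coalition for every sample: average prediction over
    # background rows with the coalition's columns replaced by the sample's
    coalition_values: dict[frozenset, np.ndarray] = {}
    for size in range(p + 1):
        for S in itertools.combinations(range(p), size):
            mixed = np.repeat(B[None, :, :], n, axis=0)  # (n, m, p)
            for j in S:
                mixed[:, :, j] = X[:, j][:, None]
            preds = predict(mixed.reshape(n * m, p)).reshape(n, m)
            coalition_values[frozenset(S)] = preds.mean(axis=1)

    phi = np.zeros((n, p))
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(p):
            weight = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for S in itertools.combinations(others, size):
                without = coalition_values[frozenset(S)]
                with_j = coalition_values[frozenset(S + (j,))]
                phi[:, j] += weight * (with_j - without)

    base = float(coalition_values[frozenset()].mean())  # == mean prediction over background
    return ShapleyMatrix(tuple(feature_names), phi, base, X)


def importance_summary(
    importance: ImportanceResult,
    shap: ShapleyMatrix,
    path: str | Path | None = None,
) -> dict:
    """Combine both attribution methods into one ranked JSON-serialisable report."""
    if importance.feature_names != shap.feature_names:
        raise ValueError("importance and Shapley results cover different feature sets")
    rank_mda = importance.ranking()
    rank_shap = shap.ranking()
    report = {
        "features": list(importance.feature_names),
        "permutation": importance.to_dict(),
        "shapley_mean_abs": shap.mean_abs().tolist(),
        "shapley_base_value": shap.base_value,
        "rank_permutation": rank_mda,
        "rank_shapley": rank_shap,
        "methods_agree_on_top": rank_mda[0] == rank_shap[0],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
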