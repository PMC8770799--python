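"""Permutation feature importance and backward feature elimination.

Importance of a feature = mean drop in a performance metric after that
feature's values are shuffled across fields, breaking its link with the
labels.  The permutation unit is a whole field-season series (block
permutation), which preserves each series' internal autocorrelation and
only destroys the field-to-label association.

Backward elimination starts from all features, repeatedly retrains
without the currently least-important feature, and keeps the removal
while the metric does not decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import evaluate_predictions
from .features import FeatureMatrix

__all__ = ["ImportanceReport", "permutation_importance", "backward_elimination"]

_METRICS = ("auc_roc", "event_accuracy", "eos_accuracy")


@dataclass
class ImportanceReport:
    feature_names: tuple[str, ...]
    importances: np.ndarray        # mean metric drop per feature
    baseline: float
    metric: str
    n_repeats: int
    seed: int

    def ranking(self) -> list[tuple[str, float]]:
        order = np.argsort(self.importances)[::-1]
        return [(self.feature_names[i], float(self.importances[i])) for i in order]


def _score(predict_fn, matrix: FeatureMatrix, metric: str) -> float:
    probs = predict_fn(matrix)
    out = evaluate_predictions(np.asarray(probs), matrix.event_starts)
    return float(out[metric])


def permutation_importance(
    predict_fn,
    matrix: FeatureMatrix,
    metric: str = "auc_roc",
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Mean metric drop when each feature is block-permuted across fields.

    ``predict_fn(matrix) -> (n_fields, n_days) probabilities`` is a
    fitted scorer (e.g. ``results.predict``).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if matrix.event_starts is None:
        raise ValueError("matrix carries no event starts")

    rng = np.random.default_rng(seed)
    baseline = _score(predict_fn, matrix, metric)
    n_features = len(matrix.feature_names)
    drops = np.zeros(n_features)
    for f in range(n_features):
        acc = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(matrix.n_fields)
            shuffled = matrix.values.copy()
            shuffled[:, :, f] = matrix.values[perm, :, f]
            permuted = FeatureMatrix(matrix.field_ids, shuffled, matrix.labels,
                                     matrix.feature_names, matrix.event_starts)
            acc += baseline - _score(predict_fn, permuted, metric)
        drops[f] = acc / n_repeats
    return ImportanceReport(matrix.feature_names, drops, baseline, metric, n_repeats, seed)


def backward_elimination(
    train_fn,
    matrix: FeatureMatrix,
    metric: str = "auc_roc",
    n_repeats: int = 3,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Iteratively drop the least important feature while the metric holds.

    ``train_fn(matrix) -> predict_fn`` trains a model on the given
    feature subset and returns its scorer.  Returns the retained
    feature names and the metric trajectory (score after each accepted
    state, starting with all features).
    """
    if len(matrix.feature_names) < 2:
        return list(matrix.feature_names), [_score(train_fn(matrix), matrix, metric)]

    current = list(matrix.feature_names)
    sub = matrix.subset_features(current)
    predict_fn = train_fn(sub)
    score = _score(predict_fn, sub, metric)
    trajectory = [score]

    while len(current) > 1:
        report = permutation_importance(predict_fn, sub, metric, n_repeats, seed)
        weakest = report.feature_names[int(np.argmin(report.importances))]
        candidate = [f for f in current if f != weakest]
        cand_sub = matrix.subset_features(candidate)
        cand_predict = train_fn(cand_sub)
        cand_score = _score(cand_predict, cand_sub, metric)
        if cand_score >= score:
            current, sub, predict_fn, score = candidate, cand_sub, cand_predict, cand_score
            trajectory.append(score)
        else:
            break
    return current, trajectory
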