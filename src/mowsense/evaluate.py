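"""Turning daily probabilities into events and scoring them.

Two views of model quality are computed, mirroring how the detector is
used operationally:

*Event level.*  Daily probabilities are decoded into discrete predicted
events (maximal above-threshold runs); a predicted start matches a true
mowing start when it falls no more than 3 days early and no more than 6
days late.  Within one window only the first prediction counts as a
true positive, every further one is a false positive.  Accuracy is
(TP + TN) / (TP + TN + FP + FN), with one TN contributed by each
field-season that has neither true nor predicted events.

*Season level.*  A field's season score aggregates its daily
probabilities (noisy-or by default, max optionally); a field scoring
above 0.5 is called mown.  EOS (end-of-season) accuracy is the fraction
of fields whose mown/not-mown status is right, and AUC-ROC ranks the
season scores against the true flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictedEvents",
    "MatchCounts",
    "probabilities_to_events",
    "match_events",
    "event_accuracy",
    "season_scores",
    "eos_accuracy",
    "auc_roc",
    "calibration_curve",
    "evaluate_predictions",
]

EARLY_TOLERANCE_DAYS = 3
LATE_TOLERANCE_DAYS = 6


@dataclass
class PredictedEvents:
    """Decoded events for one field: start days and each run's peak probability."""

    field_id: str
    starts: np.ndarray
    peak_probs: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.peak_probs = np.asarray(self.peak_probs, dtype=float)
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("predicted starts must be strictly increasing")


@dataclass
class MatchCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.TP + other.TP, self.TN + other.TN,
                           self.FP + other.FP, self.FN + other.FN)

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def probabilities_to_events(
    probs: np.ndarray,
    threshold: float = 0.5,
    min_run_days: int = 1,
    field_id: str = "",
) -> PredictedEvents:
    """Decode a daily probability vector into predicted events.

    Each maximal run of at least ``min_run_days`` consecutive days with
    probability strictly above ``threshold`` is one event starting on
    the run's first day.
    """
    probs = np.asarray(probs, dtype=float)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    above = probs > threshold
    edges = np.diff(np.concatenate(([0], above.astype(int), [0])))
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)  # exclusive
    keep = (run_ends - run_starts) >= min_run_days
    starts = run_starts[keep]
    peaks = np.array([probs[s:e].max() for s, e in zip(starts, run_ends[keep])])
    return PredictedEvents(field_id, starts, peaks)


def match_events(
    predicted_starts,
    actual_starts,
    early_tolerance: int = EARLY_TOLERANCE_DAYS,
    late_tolerance: int = LATE_TOLERANCE_DAYS,
) -> MatchCounts:
    """Match predicted to actual event starts for one field-season.

    Actual events are processed in order; each claims the earliest
    still-unmatched prediction inside its tolerance window
    [a - early_tolerance, a + late_tolerance].  Unclaimed predictions
    are false positives, unmatched actual events false negatives, and a
    season with neither contributes one true negative.  For windows that
    cannot overlap (real labels are at least 10 days apart) this equals
    the maximum-cardinality assignment.
    """
    pred = np.asarray(predicted_starts, dtype=float)
    act = np.asarray(actual_starts, dtype=float)
    if np.any(np.diff(pred) < 0) or np.any(np.diff(act) < 0):
        raise ValueError("start lists must be sorted ascending")
    if pred.size == 0 and act.size == 0:
        return MatchCounts(TN=1)

    consumed = np.zeros(pred.size, dtype=bool)
    tp = fn = 0
    for a in act:
        in_window = (~consumed) & (pred >= a - early_tolerance) & (pred <= a + late_tolerance)
        idx = np.flatnonzero(in_window)
        if idx.size:
            consumed[idx[0]] = True
            tp += 1
        else:
            fn += 1
    fp = int((~consumed).sum())
    return MatchCounts(TP=tp, FP=fp, FN=fn)


def event_accuracy(counts: MatchCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy from all-zero counts")
    return (counts.TP + counts.TN) / counts.total


def season_scores(probs: np.ndarray, method: str = "noisy_or") -> np.ndarray:
    """Season-level mowing score per field from daily probabilities.

    "noisy_or": 1 - prod(1 - p_d) -- probability that at least one day
    had an event if days were independent.  "max": the season's peak
    daily probability.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if method == "noisy_or":
        return 1.0 - np.prod(1.0 - probs, axis=1)
    if method == "max":
        return probs.max(axis=1)
    raise ValueError(f"unknown season-score method {method!r}")


def eos_accuracy(
    probs: np.ndarray,
    mown_flags: np.ndarray,
    threshold: float = 0.5,
    score_method: str = "noisy_or",
) -> float:
    """Fraction of fields whose end-of-season mown status is predicted correctly."""
    flags = np.asarray(mown_flags, dtype=bool)
    scores = season_scores(probs, score_method)
    if scores.shape[0] != flags.shape[0]:
        raise ValueError("probs and mown_flags disagree on the number of fields")
    return float(np.mean((scores > threshold) == flags))


def auc_roc(scores, flags) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    n_pos = int(flags.sum())
    n_neg = flags.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    # midranks for ties
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    u = ranks[flags].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def calibration_curve(scores, flags, n_bins: int = 10):
    """Reliability table over equal-width probability bins on [0, 1].

    Returns (mean_predicted, observed_fraction, count) arrays of length
    ``n_bins``; empty bins carry count 0 and NaN means.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    bins = np.minimum((scores * n_bins).astype(int), n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    observed = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = bins == b
        count[b] = int(mask.sum())
        if count[b]:
            mean_pred[b] = scores[mask].mean()
            observed[b] = flags[mask].mean()
    return mean_pred, observed, count


def evaluate_predictions(
    probs: np.ndarray,
    event_starts: list[np.ndarray],
    threshold: float = 0.5,
    min_run_days: int = 1,
    score_method: str = "noisy_or",
) -> dict:
    """All headline metrics for a batch of fields.

    probs: (n_fields, n_days); event_starts: per-field true start days.
    Returns event accuracy, EOS accuracy, season-score AUC, and the
    aggregated match counts.
    """
    probs = np.asarray(probs, dtype=float)
    counts = MatchCounts()
    for p, actual in zip(probs, event_starts):
        pred = probabilities_to_events(p, threshold=threshold, min_run_days=min_run_days)
        counts = counts + match_events(pred.starts, np.sort(np.asarray(actual)))
    flags = np.array([len(s) > 0 for s in event_starts])
    scores = season_scores(probs, score_method)
    out = {
        "event_accuracy": event_accuracy(counts),
        "eos_accuracy": eos_accuracy(probs, flags, score_method=score_method),
        "counts": counts,
        "season_scores": scores,
        "mown_flags": flags,
    }
    out["auc_roc"] = auc_roc(scores, flags) if 0 < flags.sum() < flags.size else float("nan")
    return out
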