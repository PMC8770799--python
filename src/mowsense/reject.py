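"""Classification with a reject option over season-level scores.

When the detector's season score for a field falls in an uncertainty
interval (t_low, t_upper) the model abstains and the field is forwarded
to a human inspector; outside the interval it commits to mown (score >=
t_upper) or not mown (score <= t_low).  The interval is fitted on
validation data so that requested true-positive and true-negative rates
are achieved among the committed decisions:

* t_upper is the score of the k-th positive in descending score order,
  k = ceil(desired_tpr * n_pos), so at least that fraction of true
  positives is retained and called mown;
* t_low is the score of the m-th negative in ascending order,
  m = ceil(desired_tnr * n_neg), symmetrically.

Scores exactly on a threshold are decided, not abstained.  Demanding
rates push the thresholds toward the middle; if they cross
(t_low >= t_upper) the interval is empty and nothing is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RejectInterval", "RejectedDecision", "fit_reject_interval", "apply_reject"]


@dataclass(frozen=True)
class RejectInterval:
    t_low: float
    t_upper: float
    desired_tpr: float
    desired_tnr: float

    def __post_init__(self) -> None:
        for name in ("t_low", "t_upper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def is_empty(self) -> bool:
        return self.t_low >= self.t_upper


@dataclass(frozen=True)
class RejectedDecision:
    field_id: str
    decision: str           # "mown" | "not_mown" | "abstain"
    season_score: float


def fit_reject_interval(
    val_scores,
    val_flags,
    desired_tpr: float,
    desired_tnr: float,
) -> RejectInterval:
    """Thresholds achieving the requested TPR/TNR on validation scores."""
    scores = np.asarray(val_scores, dtype=float)
    flags = np.asarray(val_flags, dtype=bool)
    if not (0.0 < desired_tpr <= 1.0 and 0.0 < desired_tnr <= 1.0):
        raise ValueError("desired rates must lie in (0, 1]")
    pos = scores[flags]
    neg = scores[~flags]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("validation set must contain both classes")

    k = math.ceil(desired_tpr * pos.size)
    t_upper = float(np.sort(pos)[::-1][k - 1])
    m = math.ceil(desired_tnr * neg.size)
    t_low = float(np.sort(neg)[m - 1])
    return RejectInterval(t_low=t_low, t_upper=t_upper,
                          desired_tpr=desired_tpr, desired_tnr=desired_tnr)


def apply_reject(
    scores,
    interval: RejectInterval,
    field_ids: list[str] | None = None,
    true_flags=None,
) -> tuple[list[RejectedDecision], dict]:
    """Classify-or-abstain every field; summarize the retained set.

    Returns the per-field decisions and a summary with the fraction
    rejected and, when ``true_flags`` is given, accuracy on the retained
    decisions (None if everything was rejected).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    ids = field_ids if field_ids is not None else [str(i) for i in range(scores.size)]

    decisions = []
    for fid, s in zip(ids, scores):
        if s >= interval.t_upper:
            d = "mown"
        elif s <= interval.t_low:
            d = "not_mown"
        else:
            d = "abstain"
        decisions.append(RejectedDecision(fid, d, float(s)))

    retained = [d for d in decisions if d.decision != "abstain"]
    summary = {
        "n_total": int(scores.size),
        "n_rejected": int(scores.size - len(retained)),
        "fraction_rejected": (scores.size - len(retained)) / scores.size if scores.size else 0.0,
        "retained_accuracy": None,
    }
    if true_flags is not None and retained:
        flags = {fid: bool(f) for fid, f in zip(ids, np.asarray(true_flags, dtype=bool))}
        correct = sum((d.decision == "mown") == flags[d.field_id] for d in retained)
        summary["retained_accuracy"] = correct / len(retained)
    return decisions, summary
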