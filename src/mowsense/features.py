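"""The 14-feature daily representation and its assembly into model inputs.

Per field-day the detector sees, in this fixed order:

    ndvi, cohvv, cohvh            raw (interpolated) channels
    t                             normalized day of year, doy / 365
    dt                            min-max-normalized gap in days since the
                                  previous real (non-interpolated) measurement
    cohvv_sm, cohvh_sm            EMA-smoothed coherence
    mixed_coh                     sqrt(cohvh * cohvv), the geometric mean
    ndvi_diff, cohvv_sm_diff,     difference between consecutive real
    cohvh_sm_diff                 measurements of the channel
    ndvi_der, cohvh_sm_der,       slope of the line between consecutive real
    cohvv_sm_der                  measurements (difference / days elapsed)

Difference and slope features are computed between *valid* measurements
and carried unchanged across the interpolated days in between, so the
model can tell a real change from an interpolation artefact; ``dt``
plays the same role for the sampling pattern itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DailyGrid, EventLabel, SeasonWindow

__all__ = [
    "FEATURE_NAMES",
    "NormalizationStats",
    "FeatureMatrix",
    "mixed_coherence",
    "normalized_doy",
    "normalized_gap",
    "diff_and_slope",
    "fit_normalization_stats",
    "build_feature_matrix",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ndvi", "cohvv", "cohvh", "t", "dt",
    "cohvv_sm", "cohvh_sm", "mixed_coh",
    "ndvi_diff", "cohvv_sm_diff", "cohvh_sm_diff",
    "ndvi_der", "cohvh_sm_der", "cohvv_sm_der",
)

#: days a daily label stays on after an event start, matching the
#: -3/+6-day evaluation tolerance
DEFAULT_LABEL_WIDTH = 7


@dataclass(frozen=True)
class NormalizationStats:
    """Min-max scaling bounds (in days) for the measurement-gap feature.

    Fitted on training fields only; unseen gaps outside the range clip
    to [0, 1] instead of erroring.
    """

    min_diff: float
    max_diff: float

    def __post_init__(self) -> None:
        if not 0 <= self.min_diff < self.max_diff:
            raise ValueError(
                f"need 0 <= min_diff < max_diff, got ({self.min_diff}, {self.max_diff})"
            )


def mixed_coherence(cohvh, cohvv):
    """Geometric mean sqrt(cohvh * cohvv) -- a single overall coherence trend."""
    cohvh = np.asarray(cohvh, dtype=float)
    cohvv = np.asarray(cohvv, dtype=float)
    if np.any(cohvh < 0) or np.any(cohvv < 0):
        raise ValueError("coherence values must be non-negative")
    out = np.sqrt(cohvh * cohvv)
    return float(out) if out.ndim == 0 else out


def normalized_doy(day_of_year) -> float | np.ndarray:
    """t = day_of_year / 365 with January 1st as day 1."""
    d = np.asarray(day_of_year, dtype=float)
    if np.any(d < 1) or np.any(d > 366):
        raise ValueError(f"day_of_year outside 1..366: {day_of_year!r}")
    out = d / 365.0
    return float(out) if out.ndim == 0 else out


def normalized_gap(diff, stats: NormalizationStats):
    """Min-max scale a gap in days, clipping unseen extremes into [0, 1]."""
    d = np.asarray(diff, dtype=float)
    if np.any(d < 0):
        raise ValueError("gaps must be non-negative")
    out = np.clip((d - stats.min_diff) / (stats.max_diff - stats.min_diff), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def diff_and_slope(values: np.ndarray, valid_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-day difference and slope between consecutive valid measurements.

    At a valid day d with previous valid day p: diff = v[d] - v[p] and
    slope = diff / (d - p); both are carried unchanged on the following
    interpolated days until the next valid day.  The first valid day
    (and everything before it) gets 0.
    """
    values = np.asarray(values, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if values.shape != valid_mask.shape:
        raise ValueError("values and valid_mask must have the same length")
    n = values.size
    diff = np.zeros(n)
    slope = np.zeros(n)
    valid_days = np.flatnonzero(valid_mask)
    for p, d in zip(valid_days, valid_days[1:]):
        dv = values[d] - values[p]
        diff[d:] = dv
        slope[d:] = dv / (d - p)
    return diff, slope


def _gap_series(grid: DailyGrid) -> np.ndarray:
    """Raw per-day gap (days) between consecutive real measurements, carried forward."""
    gaps = np.zeros(grid.n_days)
    valid_days = np.flatnonzero(grid.any_valid)
    for p, d in zip(valid_days, valid_days[1:]):
        gaps[d:] = d - p
    return gaps


def fit_normalization_stats(grids: list[DailyGrid]) -> NormalizationStats:
    """Gap-scaling bounds from the training fields' real-measurement spacing."""
    all_gaps: list[float] = []
    for g in grids:
        vd = np.flatnonzero(g.any_valid)
        all_gaps.extend(np.diff(vd).tolist())
    if not all_gaps:
        raise ValueError("no measurement gaps found in training grids")
    lo, hi = float(min(all_gaps)), float(max(all_gaps))
    if lo == hi:
        lo, hi = 0.0, hi if hi > 0 else 1.0
    return NormalizationStats(min_diff=lo, max_diff=hi)


@dataclass
class FeatureMatrix:
    """Model-ready tensor: n_fields x n_days x 14 features plus daily labels."""

    field_ids: list[str]
    values: np.ndarray            # (n_fields, n_days, 14)
    labels: np.ndarray            # (n_fields, n_days) in {0, 1}
    feature_names: tuple[str, ...] = FEATURE_NAMES
    event_starts: list[np.ndarray] | None = None   # per-field day offsets

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        nf = len(self.field_ids)
        if self.values.shape[0] != nf or self.labels.shape[:2] != self.values.shape[:2]:
            raise ValueError("field_ids, values and labels shapes are inconsistent")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {self.values.shape[2]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")

    @property
    def n_fields(self) -> int:
        return len(self.field_ids)

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @property
    def mown_flags(self) -> np.ndarray:
        return self.labels.any(axis=1)

    def subset_fields(self, index) -> "FeatureMatrix":
        index = np.asarray(index)
        starts = [self.event_starts[i] for i in index] if self.event_starts is not None else None
        return FeatureMatrix(
            field_ids=[self.field_ids[i] for i in index],
            values=self.values[index],
            labels=self.labels[index],
            feature_names=self.feature_names,
            event_starts=starts,
        )

    def subset_features(self, names: list[str]) -> "FeatureMatrix":
        ix = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            field_ids=self.field_ids,
            values=self.values[:, :, ix],
            labels=self.labels,
            feature_names=tuple(names),
            event_starts=self.event_starts,
        )


def _field_features(grid: DailyGrid, stats: NormalizationStats, window: SeasonWindow) -> np.ndarray:
    n = grid.n_days
    doy0 = window.start_date.timetuple().tm_yday
    t = normalized_doy(doy0 + np.arange(n))
    dt = normalized_gap(_gap_series(grid), stats)
    mixed = mixed_coherence(grid.cohvh, grid.cohvv)
    ndvi_diff, ndvi_der = diff_and_slope(grid.ndvi, grid.ndvi_valid)
    vv_diff, vv_der = diff_and_slope(grid.cohvv_sm, grid.cohvv_valid)
    vh_diff, vh_der = diff_and_slope(grid.cohvh_sm, grid.cohvh_valid)
    cols = {
        "ndvi": grid.ndvi, "cohvv": grid.cohvv, "cohvh": grid.cohvh,
        "t": t, "dt": dt,
        "cohvv_sm": grid.cohvv_sm, "cohvh_sm": grid.cohvh_sm, "mixed_coh": mixed,
        "ndvi_diff": ndvi_diff, "cohvv_sm_diff": vv_diff, "cohvh_sm_diff": vh_diff,
        "ndvi_der": ndvi_der, "cohvh_sm_der": vh_der, "cohvv_sm_der": vv_der,
    }
    return np.column_stack([cols[name] for name in FEATURE_NAMES])


def save_matrix(path, matrix: FeatureMatrix) -> None:
    """Persist a FeatureMatrix to ``.npz`` (event starts as ';'-joined strings)."""
    starts = matrix.event_starts or [np.array([], dtype=int)] * matrix.n_fields
    np.savez_compressed(
        path,
        values=matrix.values,
        labels=matrix.labels,
        field_ids=np.array(matrix.field_ids, dtype="U"),
        feature_names=np.array(matrix.feature_names, dtype="U"),
        event_starts=np.array([";".join(str(int(s)) for s in st) for st in starts], dtype="U"),
    )


def load_matrix(path) -> FeatureMatrix:
    with np.load(path) as z:
        starts = [
            np.array([int(x) for x in s.split(";") if x], dtype=int)
            for s in z["event_starts"]
        ]
        return FeatureMatrix(
            field_ids=[str(f) for f in z["field_ids"]],
            values=z["values"],
            labels=z["labels"],
            feature_names=tuple(str(n) for n in z["feature_names"]),
            event_starts=starts,
        )


def build_feature_matrix(
    grids: list[DailyGrid],
    labels: list[EventLabel],
    stats: NormalizationStats,
    window: SeasonWindow | None = None,
    label_width: int = DEFAULT_LABEL_WIDTH,
) -> FeatureMatrix:
    """Assemble daily features and binary daily labels for a set of fields.

    The daily label is 1 on days [s, s + label_width - 1] for each event
    start s (clipped at the season end), else 0.
    """
    window = window or (grids[0].window if grids else SeasonWindow())
    by_id = {l.field_id: l for l in labels}
    missing = [g.field_id for g in grids if g.field_id not in by_id]
    if missing:
        raise KeyError(f"fields missing from labels: {missing[:5]}")

    values, ylab, starts_all = [], [], []
    for g in grids:
        values.append(_field_features(g, stats, window))
        starts = by_id[g.field_id].start_days(window)
        y = np.zeros(window.n_days)
        for s in starts:
            y[max(0, s): min(window.n_days, s + label_width)] = 1.0
        ylab.append(y)
        starts_all.append(starts)

    return FeatureMatrix(
        field_ids=[g.field_id for g in grids],
        values=np.stack(values) if values else np.zeros((0, window.n_days, len(FEATURE_NAMES))),
        labels=np.stack(ylab) if ylab else np.zeros((0, window.n_days)),
        event_starts=starts_all,
    )
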