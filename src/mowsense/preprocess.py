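"""NDVI outlier filtering, coherence smoothing, daily interpolation.

The raw per-field series are sparse and noisy.  Three standard repairs
are applied before any feature derivation:

1.  *NDVI outlier removal.*  Cloud-mask failures produce isolated NDVI
    samples that crash toward zero and recover immediately.  For every
    three consecutive valid NDVI measurements (ndvi_1, ndvi_2, ndvi_3)
    spanning at most 10 days, the middle one is discarded when

        ndvi_3 - 2 * ndvi_2 + ndvi_1 >= 0.6

    A genuine mowing cut also drops NDVI, but its signature needs about
    10 days to recover, so the short-span guard keeps real events.

2.  *Coherence smoothing.*  Either an exponential moving average
    (default, alpha = 1/3) or a centred moving average (default width 7)
    applied to the valid coherence measurements, before interpolation.

3.  *Daily interpolation.*  Each channel is linearly interpolated onto
    the fixed season grid; outside the observed range the nearest value
    is held constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DailyGrid, FieldSeries, Observation, SeasonWindow

__all__ = [
    "SmoothingConfig",
    "ndvi_from_bands",
    "filter_ndvi_outliers",
    "ema_smooth",
    "moving_average_smooth",
    "interpolate_daily",
]

#: triplet curvature above which the middle NDVI sample is an outlier
OUTLIER_THRESHOLD = 0.6
#: triplets wider than this (first to third sample) are never filtered
OUTLIER_MAX_SPAN_DAYS = 10

#: season-constant fallbacks for a channel with zero valid measurements
FALLBACK_NDVI = 0.5
FALLBACK_COHERENCE = 0.3


@dataclass(frozen=True)
class SmoothingConfig:
    """Coherence smoothing settings.

    method: "ema" (exponential moving average) or "moving_average".
    alpha: EMA weight on the newest sample, in (0, 1]; smaller = smoother.
    filter_width: odd centred-window width for the moving average.
    """

    method: str = "ema"
    alpha: float = 1.0 / 3.0
    filter_width: int = 7

    def __post_init__(self) -> None:
        if self.method not in ("ema", "moving_average"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.filter_width < 3 or self.filter_width % 2 == 0:
            raise ValueError(f"filter_width must be odd and >= 3, got {self.filter_width}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.method == "ema":
            return ema_smooth(values, self.alpha)
        return moving_average_smooth(values, self.filter_width)


def ndvi_from_bands(band4: float, band8: float) -> float:
    """NDVI = (band8 - band4) / (band8 + band4) from red / near-infrared reflectances."""
    if band4 < 0 or band8 < 0:
        raise ValueError("reflectances must be non-negative")
    denom = band8 + band4
    if denom == 0:
        raise ValueError("band4 + band8 must be positive")
    return (band8 - band4) / denom


def filter_ndvi_outliers(
    series: FieldSeries,
    threshold: float = OUTLIER_THRESHOLD,
    max_span_days: int = OUTLIER_MAX_SPAN_DAYS,
) -> tuple[FieldSeries, list[int]]:
    """Remove cloud-mask NDVI outliers via the triplet curvature rule.

    Every window of three consecutive *valid* NDVI measurements is
    evaluated on the original values; all flagged middles are removed in
    a single pass (no cascading re-evaluation), so the result does not
    depend on scan order.  Returns the cleaned series and the indices
    (into ``series.observations``) whose NDVI was dropped.

    Fewer than three valid NDVI samples: returned unchanged.
    """
    valid = [
        (i, o.date, o.ndvi)
        for i, o in enumerate(series.observations)
        if o.ndvi is not None and not np.isnan(o.ndvi)
    ]
    if len(valid) < 3:
        return series, []

    flagged: set[int] = set()
    for (i1, d1, v1), (i2, _d2, v2), (i3, d3, v3) in zip(valid, valid[1:], valid[2:]):
        span = (d3 - d1).days
        if span <= max_span_days and (v3 - 2.0 * v2 + v1) >= threshold:
            flagged.add(i2)

    if not flagged:
        return series, []

    cleaned: list[Observation] = []
    for i, o in enumerate(series.observations):
        if i in flagged:
            # drop only the NDVI value; coherence on the same date survives
            if o.cohvv is not None or o.cohvh is not None:
                cleaned.append(Observation(o.date, None, o.cohvv, o.cohvh))
        else:
            cleaned.append(o)
    return FieldSeries(series.field_id, cleaned, series.area_ha), sorted(flagged)


def ema_smooth(values, alpha: float) -> np.ndarray:
    """Exponential moving average: out_n = alpha * in_n + (1 - alpha) * out_{n-1}.

    Initialised at the first sample (out_1 = in_1).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    out = np.empty_like(values)
    out[0] = values[0]
    for n in range(1, values.size):
        out[n] = alpha * values[n] + (1.0 - alpha) * out[n - 1]
    return out


def moving_average_smooth(values, filter_width: int) -> np.ndarray:
    """Centred moving average, window truncated symmetrically at the edges.

    At position i the window is i +/- h with h = min(filter_width // 2,
    distance to the nearer edge), so the output length equals the input
    length and the window stays centred.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    if filter_width < 3 or filter_width % 2 == 0:
        raise ValueError(f"filter_width must be odd and >= 3, got {filter_width}")
    half = filter_width // 2
    out = np.empty_like(values)
    n = values.size
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def _interp_to_days(days: np.ndarray, vals: np.ndarray, n_days: int, fallback: float):
    """Linear interpolation to the integer grid, constant extension at the ends."""
    mask = np.zeros(n_days, dtype=bool)
    if vals.size == 0:
        return np.full(n_days, fallback), mask
    mask[days] = True
    grid = np.interp(np.arange(n_days), days, vals)  # np.interp holds edge values
    return grid, mask


def interpolate_daily(
    series: FieldSeries,
    window: SeasonWindow,
    smoothing: SmoothingConfig | None = None,
) -> DailyGrid:
    """Resample a sparse field series onto the dense season grid.

    Coherence smoothing is applied to the valid measurements *before*
    interpolation.  Observations outside the window are ignored.  A
    channel with no valid measurement in the window is filled with a
    season constant (NDVI 0.5, coherence 0.3).
    """
    if window.n_days < 2:
        raise ValueError("season window shorter than 2 days")
    smoothing = smoothing or SmoothingConfig()

    def _channel(name: str) -> tuple[np.ndarray, np.ndarray]:
        dates, vals = series.channel(name)
        days = np.array([window.day_of(d) for d in dates], dtype=int)
        keep = (days >= 0) & (days < window.n_days)
        return days[keep], vals[keep]

    nd_days, nd_vals = _channel("ndvi")
    vv_days, vv_vals = _channel("cohvv")
    vh_days, vh_vals = _channel("cohvh")

    ndvi, ndvi_valid = _interp_to_days(nd_days, nd_vals, window.n_days, FALLBACK_NDVI)
    cohvv, vv_valid = _interp_to_days(vv_days, vv_vals, window.n_days, FALLBACK_COHERENCE)
    cohvh, vh_valid = _interp_to_days(vh_days, vh_vals, window.n_days, FALLBACK_COHERENCE)

    vv_sm_vals = smoothing.apply(vv_vals) if vv_vals.size else vv_vals
    vh_sm_vals = smoothing.apply(vh_vals) if vh_vals.size else vh_vals
    cohvv_sm, _ = _interp_to_days(vv_days, vv_sm_vals, window.n_days, FALLBACK_COHERENCE)
    cohvh_sm, _ = _interp_to_days(vh_days, vh_sm_vals, window.n_days, FALLBACK_COHERENCE)

    return DailyGrid(
        field_id=series.field_id,
        window=window,
        ndvi=ndvi,
        cohvv=cohvv,
        cohvh=cohvh,
        cohvv_sm=cohvv_sm,
        cohvh_sm=cohvh_sm,
        ndvi_valid=ndvi_valid,
        cohvv_valid=vv_valid,
        cohvh_valid=vh_valid,
    )
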