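"""Synthetic labelled field-seasons.

No mowing dataset is publicly deposited, so the package ships a
generator that reproduces the phenomenology the detector is built
around, one field-season at a time:

* an unmown grassland's NDVI follows a half-oval seasonal curve (rise,
  plateau, decay) riding on measurement noise;
* a mowing event cuts NDVI sharply (the grass is gone) with a linear
  regrowth over a few weeks, and raises interferometric coherence (the
  ground stays put) for roughly 24-36 days before it decays back;
* Sentinel-2 NDVI is sampled every ~4 days but ~75% of samples are lost
  to clouds, and a rare surviving sample is a cloud-mask outlier that
  crashes toward zero for a single acquisition;
* Sentinel-1 coherence arrives every 6 days; rain days knock coherence
  down multiplicatively.

Everything is driven by ``numpy.random.Generator`` streams spawned per
field, so a dataset is bitwise reproducible from its seed and any field
can be regenerated in isolation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _dc_field

import numpy as np

from .types import EventLabel, FieldSeries, Observation, SeasonWindow

__all__ = ["SimConfig", "SimTruth", "simulate_field", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the Estonian grassland monitoring setting: ~95% of
    fields mown at least once, ~75% of NDVI acquisitions cloud-invalid,
    6-day SAR cadence, and a post-mowing coherence rise persisting
    24-36 days.
    """

    n_fields: int = 1000
    mown_fraction: float = 0.95
    max_events_per_field: int = 3
    ndvi_invalid_fraction: float = 0.75
    outlier_rate: float = 0.001
    s1_cadence_days: int = 6
    s2_cadence_days: int = 4
    event_ndvi_drop_range: tuple[float, float] = (0.2, 0.45)
    event_coh_rise_range: tuple[float, float] = (0.10, 0.30)
    event_persistence_days_range: tuple[int, int] = (24, 36)
    regrowth_days_range: tuple[int, int] = (25, 40)
    noise_sd_ndvi: float = 0.02
    noise_sd_coh: float = 0.03
    rain_day_rate: float = 0.08
    seed: int = 0
    window: SeasonWindow = _dc_field(default_factory=SeasonWindow)

    def __post_init__(self) -> None:
        for name in ("mown_fraction", "ndvi_invalid_fraction", "outlier_rate", "rain_day_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("event_ndvi_drop_range", "event_coh_rise_range",
                     "event_persistence_days_range", "regrowth_days_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} lower bound {lo} exceeds upper bound {hi}")
        if self.s1_cadence_days < 1 or self.s2_cadence_days < 1:
            raise ValueError("cadences must be >= 1 day")
        if self.n_fields < 0 or self.max_events_per_field < 1:
            raise ValueError("n_fields must be >= 0 and max_events_per_field >= 1")


@dataclass
class SimTruth:
    """Noise-free ground truth for one simulated field-season."""

    field_id: str
    event_starts: np.ndarray          # day offsets, sorted
    latent_ndvi: np.ndarray           # length n_days
    latent_cohvv: np.ndarray
    latent_cohvh: np.ndarray


def _half_oval(n_days: int, n_min: float, n_max: float, t_mid: float, h: float) -> np.ndarray:
    t = np.arange(n_days, dtype=float)
    arg = 1.0 - ((t - t_mid) / h) ** 2
    return n_min + (n_max - n_min) * np.sqrt(np.clip(arg, 0.0, None))


def _draw_event_starts(rng: np.random.Generator, n_events: int, cfg: SimConfig) -> np.ndarray:
    """Sorted event starts with a summer-weighted prior and minimum separation."""
    n_days = cfg.window.n_days
    days = np.arange(n_days)
    # triangular weight peaking mid-season: mowing is a summer activity
    peak = 0.45 * n_days
    w = 1.0 - np.abs(days - peak) / n_days
    # keep starts clear of the season edges so the signature fits inside
    w[:15] = 0.0
    w[-20:] = 0.0
    w = w / w.sum()
    min_sep = cfg.regrowth_days_range[1]
    for _ in range(200):
        starts = np.sort(rng.choice(days, size=n_events, replace=False, p=w))
        if n_events == 1 or np.all(np.diff(starts) >= min_sep):
            return starts
    # fall back to an evenly spaced grid jittered inside the allowed band
    lo, hi = 15, n_days - 21
    grid = np.linspace(lo, hi - (n_events - 1) * min_sep, n_events)
    return np.sort(grid.astype(int) + np.arange(n_events) * min_sep)


def simulate_field(
    config: SimConfig,
    field_index: int,
    rng: np.random.Generator,
    n_events: int | None = None,
) -> tuple[FieldSeries, EventLabel, SimTruth]:
    """Generate one labelled field-season.

    ``n_events=None`` draws the mown status from ``mown_fraction`` and
    then an event count uniform on 1..max_events_per_field;
    ``simulate_dataset`` passes explicit counts so dataset-level
    proportions are exact.
    """
    cfg = config
    n_days = cfg.window.n_days
    field_id = f"F{field_index:05d}"

    if n_events is None:
        mown = rng.random() < cfg.mown_fraction
        n_events = int(rng.integers(1, cfg.max_events_per_field + 1)) if mown else 0

    # --- latent curves ---------------------------------------------------
    n_min = rng.uniform(0.1, 0.3)
    n_max = rng.uniform(0.6, 0.9)
    t_mid = rng.uniform(90, 130)
    h = rng.uniform(80, 120)
    ndvi = _half_oval(n_days, n_min, n_max, t_mid, h)

    base_vv = rng.uniform(0.15, 0.40)
    base_vh = base_vv * rng.uniform(0.6, 0.9)
    cohvv = np.full(n_days, base_vv)
    cohvh = np.full(n_days, base_vh)

    starts = _draw_event_starts(rng, n_events, cfg) if n_events else np.array([], dtype=int)
    t = np.arange(n_days, dtype=float)
    for s in starts:
        drop = rng.uniform(*cfg.event_ndvi_drop_range)
        rise = rng.uniform(*cfg.event_coh_rise_range)
        persist = int(rng.integers(cfg.event_persistence_days_range[0],
                                   cfg.event_persistence_days_range[1] + 1))
        regrow = int(rng.integers(cfg.regrowth_days_range[0],
                                  cfg.regrowth_days_range[1] + 1))
        rel = t - s
        ndvi -= drop * np.clip(1.0 - rel / regrow, 0.0, None) * (rel >= 0)
        coh_bump = rise * np.clip(1.0 - rel / persist, 0.0, None) * (rel >= 0)
        cohvv += coh_bump
        cohvh += coh_bump

    ndvi = np.clip(ndvi, -1.0, 1.0)
    cohvv = np.clip(cohvv, 0.0, 1.0)
    cohvh = np.clip(cohvh, 0.0, 1.0)

    # --- sparse, noisy sampling ------------------------------------------
    obs: dict[int, dict[str, float]] = {}

    s2_phase = int(rng.integers(cfg.s2_cadence_days))
    prev_was_outlier = False  # cloud-mask outliers never form a sequence
    for d in range(s2_phase, n_days, cfg.s2_cadence_days):
        if rng.random() < cfg.ndvi_invalid_fraction:
            prev_was_outlier = False
            continue
        if not prev_was_outlier and rng.random() < cfg.outlier_rate:
            val = rng.uniform(0.0, 0.45 * ndvi[d] + 0.1)
            prev_was_outlier = True
        else:
            val = ndvi[d] + rng.normal(0.0, cfg.noise_sd_ndvi)
            prev_was_outlier = False
        obs.setdefault(d, {})["ndvi"] = float(np.clip(val, -1.0, 1.0))

    s1_phase = int(rng.integers(cfg.s1_cadence_days))
    for d in range(s1_phase, n_days, cfg.s1_cadence_days):
        rain = rng.uniform(0.4, 0.8) if rng.random() < cfg.rain_day_rate else 1.0
        vv = cohvv[d] * rain + rng.normal(0.0, cfg.noise_sd_coh)
        vh = cohvh[d] * rain + rng.normal(0.0, cfg.noise_sd_coh)
        rec = obs.setdefault(d, {})
        rec["cohvv"] = float(np.clip(vv, 0.0, 1.0))
        rec["cohvh"] = float(np.clip(vh, 0.0, 1.0))

    observations = [
        Observation(
            date=cfg.window.date_of(d),
            ndvi=rec.get("ndvi"),
            cohvv=rec.get("cohvv"),
            cohvh=rec.get("cohvh"),
        )
        for d, rec in sorted(obs.items())
    ]

    series = FieldSeries(field_id, observations)
    label = EventLabel(field_id, [cfg.window.date_of(s) for s in starts])
    truth = SimTruth(field_id, starts, ndvi, cohvv, cohvh)
    return series, label, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[FieldSeries], list[EventLabel], list[SimTruth]]:
    """Generate a full labelled dataset.

    Exactly ``round(n_fields * mown_fraction)`` fields carry at least
    one event; which fields, and everything else, follows from the seed.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    n_mown = int(round(cfg.n_fields * cfg.mown_fraction))
    mown_ix = set(assign_rng.permutation(cfg.n_fields)[:n_mown].tolist())

    series_all, labels_all, truths_all = [], [], []
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_fields + 1)[1:]
    for i in range(cfg.n_fields):
        rng = np.random.default_rng(child_seeds[i])
        if i in mown_ix:
            n_events = int(rng.integers(1, cfg.max_events_per_field + 1))
        else:
            n_events = 0
        s, l, tr = simulate_field(cfg, i, rng, n_events=n_events)
        series_all.append(s)
        labels_all.append(l)
        truths_all.append(tr)
    return series_all, labels_all, truths_all
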