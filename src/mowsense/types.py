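"""Core domain containers for field-season time series and labels.

A *field-season* is the unit of analysis: one grassland parcel observed
through one vegetation season (by default the 215 days from April 1 to
the end of October).  Observations are sparse and irregular -- optical
NDVI samples are mostly lost to clouds, SAR coherence arrives on a
roughly 6-day repeat cycle -- so the containers here tolerate missing
values; the preprocessing stage turns them into a dense daily grid.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Observation",
    "FieldSeries",
    "EventLabel",
    "SeasonWindow",
    "DailyGrid",
]

#: minimum number of days between two mowing events on the same field;
#: the spectral/coherence signature of a cut needs about this long to recover.
MIN_EVENT_SEPARATION_DAYS = 10


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class Observation:
    """One dated acquisition over a field.

    Any of the three channels may be missing (``None``): NDVI comes from
    Sentinel-2 and is usually cloud-masked away, while the two coherence
    channels come from Sentinel-1 and share acquisition dates.  A
    coherence value dated X describes image pair (X, X+6) -- the
    forward-looking convention; it is indexed at day X.
    """

    date: _dt.date
    ndvi: float | None = None
    cohvv: float | None = None
    cohvh: float | None = None

    def __post_init__(self) -> None:
        if _is_missing(self.ndvi) and _is_missing(self.cohvv) and _is_missing(self.cohvh):
            raise ValueError(f"observation on {self.date} has no values at all")
        if not _is_missing(self.ndvi) and not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(f"ndvi {self.ndvi!r} outside [-1, 1] on {self.date}")
        for name in ("cohvv", "cohvh"):
            v = getattr(self, name)
            if not _is_missing(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v!r} outside [0, 1] on {self.date}")


@dataclass
class FieldSeries:
    """Date-ordered sparse observations for one field-season."""

    field_id: str
    observations: list[Observation]
    area_ha: float | None = None

    def __post_init__(self) -> None:
        dates = [o.date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"field {self.field_id}: observation dates not strictly increasing")

    def __len__(self) -> int:
        return len(self.observations)

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (dates-as-objects array, values) for the valid samples of one channel."""
        dates, vals = [], []
        for o in self.observations:
            v = getattr(o, name)
            if not _is_missing(v):
                dates.append(o.date)
                vals.append(float(v))
        return np.array(dates, dtype=object), np.array(vals, dtype=float)


@dataclass
class EventLabel:
    """Ground-truth mowing starts for one field-season (possibly none)."""

    field_id: str
    mowing_starts: list[_dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = self.mowing_starts
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError(f"field {self.field_id}: mowing starts not strictly increasing")
        if any((b - a).days < MIN_EVENT_SEPARATION_DAYS for a, b in zip(s, s[1:])):
            raise ValueError(
                f"field {self.field_id}: consecutive mowing starts closer than "
                f"{MIN_EVENT_SEPARATION_DAYS} days"
            )

    @property
    def mown_flag(self) -> bool:
        return len(self.mowing_starts) > 0

    def start_days(self, window: "SeasonWindow") -> np.ndarray:
        """Event starts as 0-based day offsets within ``window``."""
        return np.array([window.day_of(d) for d in self.mowing_starts], dtype=int)


@dataclass(frozen=True)
class SeasonWindow:
    """The fixed daily axis of a vegetation season.

    Defaults to 215 days starting April 1 -- the April-through-October
    vegetation season; winter acquisitions fall outside and are dropped.
    """

    start_date: _dt.date = _dt.date(2018, 4, 1)
    n_days: int = 215

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError(f"season window needs at least 2 days, got {self.n_days}")

    def day_of(self, date: _dt.date) -> int:
        return (date - self.start_date).days

    def date_of(self, day: int) -> _dt.date:
        return self.start_date + _dt.timedelta(days=int(day))

    def contains(self, date: _dt.date) -> bool:
        return 0 <= self.day_of(date) < self.n_days

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.n_days)


@dataclass
class DailyGrid:
    """Dense daily representation of one field-season after interpolation.

    All value arrays have length ``n_days`` with no missing entries; the
    validity masks are True exactly on days carrying a real (non
    interpolated) measurement of the corresponding channel.  The
    ``cohvv_sm``/``cohvh_sm`` channels are the coherence series smoothed
    (on the real measurements, before interpolation).
    """

    field_id: str
    window: SeasonWindow
    ndvi: np.ndarray
    cohvv: np.ndarray
    cohvh: np.ndarray
    cohvv_sm: np.ndarray
    cohvh_sm: np.ndarray
    ndvi_valid: np.ndarray
    cohvv_valid: np.ndarray
    cohvh_valid: np.ndarray

    def __post_init__(self) -> None:
        n = self.window.n_days
        for name in ("ndvi", "cohvv", "cohvh", "cohvv_sm", "cohvh_sm",
                     "ndvi_valid", "cohvv_valid", "cohvh_valid"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        for name in ("ndvi", "cohvv", "cohvh", "cohvv_sm", "cohvh_sm"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values after interpolation")

    @property
    def n_days(self) -> int:
        return self.window.n_days

    @property
    def any_valid(self) -> np.ndarray:
        """Days on which at least one channel has a real measurement."""
        return self.ndvi_valid | self.cohvv_valid | self.cohvh_valid
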