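"""Delimited-text readers and writers.

All on-disk formats are plain CSV with ISO-8601 dates and empty cells
for missing values:

* field series:  field_id, date, ndvi, cohvv, cohvh
* event labels:  field_id, start_date   (empty start_date = never mown;
  a mown field has one row per event)
* predictions:   field_id, event_starts (semicolon-joined day offsets),
  p000..p{n_days-1} daily probabilities
* daily grids:   one row per field-day with all channels and masks
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EventLabel, FieldSeries, Observation, SeasonWindow

__all__ = [
    "read_field_series", "write_field_series",
    "read_labels", "write_labels",
    "read_predictions", "write_predictions",
]

log = logging.getLogger("mowsense")

_SERIES_COLUMNS = ["field_id", "date", "ndvi", "cohvv", "cohvh"]


def _parse_float(cell: str, name: str, lineno: int) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"line {lineno}: cannot parse {name}={cell!r}") from None


def read_field_series(path: str | Path) -> list[FieldSeries]:
    """Read sparse per-field observations; one FieldSeries per field_id.

    Rows may arrive in any order; observations come back sorted by date.
    Malformed rows and out-of-range values raise with the line number.
    """
    path = Path(path)
    rows: dict[str, list[tuple[_dt.date, float | None, float | None, float | None]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _SERIES_COLUMNS:
            raise ValueError(f"{path}: expected header {','.join(_SERIES_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(_SERIES_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(_SERIES_COLUMNS)} cells, "
                                 f"got {len(row)}")
            fid = row[0].strip()
            try:
                date = _dt.date.fromisoformat(row[1].strip())
            except ValueError:
                raise ValueError(f"line {lineno}: bad date {row[1]!r}") from None
            vals = [_parse_float(row[i], _SERIES_COLUMNS[i], lineno) for i in (2, 3, 4)]
            if fid not in rows:
                rows[fid] = []
                order.append(fid)
            rows[fid].append((date, *vals))

    out = []
    for fid in order:
        obs = []
        for date, ndvi, vv, vh in sorted(rows[fid], key=lambda r: r[0]):
            try:
                obs.append(Observation(date, ndvi, vv, vh))
            except ValueError as e:
                raise ValueError(f"field {fid}: {e}") from None
        out.append(FieldSeries(fid, obs))
    log.info("read %d fields / %d observations from %s",
             len(out), sum(len(s) for s in out), path)
    return out


def write_field_series(path: str | Path, series: list[FieldSeries]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SERIES_COLUMNS)
        for s in series:
            for o in s.observations:
                w.writerow([
                    s.field_id, o.date.isoformat(),
                    *("" if v is None else f"{v:.8g}" for v in (o.ndvi, o.cohvv, o.cohvh)),
                ])


def read_labels(path: str | Path) -> list[EventLabel]:
    df = pd.read_csv(path, dtype={"field_id": str}, keep_default_na=False)
    out = []
    for fid, group in df.groupby("field_id", sort=False):
        starts = sorted(
            _dt.date.fromisoformat(s) for s in group["start_date"] if s.strip() != ""
        )
        out.append(EventLabel(str(fid), starts))
    return out


def write_labels(path: str | Path, labels: list[EventLabel]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["field_id", "start_date"])
        for l in labels:
            if not l.mowing_starts:
                w.writerow([l.field_id, ""])
            for d in l.mowing_starts:
                w.writerow([l.field_id, d.isoformat()])


def write_predictions(
    path: str | Path,
    field_ids: list[str],
    probs: np.ndarray,
    event_starts: list | None = None,
    n_days: int | None = None,
) -> None:
    """Write per-field daily probabilities (8 significant digits) and decoded starts."""
    probs = np.asarray(probs, dtype=float)
    n_days = n_days or (probs.shape[1] if probs.ndim == 2 else SeasonWindow().n_days)
    if probs.ndim != 2 or probs.shape != (len(field_ids), n_days):
        raise ValueError(f"probs must have shape ({len(field_ids)}, {n_days}), "
                         f"got {probs.shape}")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if event_starts is None:
        event_starts = [[] for _ in field_ids]
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["field_id", "event_starts"] + [f"p{d:03d}" for d in range(n_days)])
        for fid, starts, p in zip(field_ids, event_starts, probs):
            w.writerow([fid, ";".join(str(int(s)) for s in starts)]
                       + [f"{v:.8g}" for v in p])


def read_predictions(path: str | Path) -> tuple[list[str], np.ndarray, list[np.ndarray]]:
    df = pd.read_csv(path, dtype={"field_id": str, "event_starts": str},
                     keep_default_na=False)
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    probs = df[pcols].to_numpy(dtype=float)
    starts = [
        np.array([int(x) for x in s.split(";") if x != ""], dtype=int)
        for s in df["event_starts"]
    ]
    return df["field_id"].tolist(), probs, starts


def read_grids(path: str | Path, window: SeasonWindow | None = None):
    from .types import DailyGrid

    df = pd.read_csv(path, dtype={"field_id": str})
    grids = []
    for fid, g in df.groupby("field_id", sort=False):
        g = g.sort_values("day")
        win = window or SeasonWindow(n_days=len(g))
        grids.append(DailyGrid(
            field_id=str(fid), window=win,
            ndvi=g["ndvi"].to_numpy(), cohvv=g["cohvv"].to_numpy(),
            cohvh=g["cohvh"].to_numpy(), cohvv_sm=g["cohvv_sm"].to_numpy(),
            cohvh_sm=g["cohvh_sm"].to_numpy(),
            ndvi_valid=g["ndvi_valid"].to_numpy().astype(bool),
            cohvv_valid=g["cohvv_valid"].to_numpy().astype(bool),
            cohvh_valid=g["cohvh_valid"].to_numpy().astype(bool),
        ))
    return grids


def write_grids(path: str | Path, grids) -> None:
    frames = []
    for g in grids:
        frames.append(pd.DataFrame({
            "field_id": g.field_id, "day": np.arange(g.n_days),
            "ndvi": g.ndvi, "cohvv": g.cohvv, "cohvh": g.cohvh,
            "cohvv_sm": g.cohvv_sm, "cohvh_sm": g.cohvh_sm,
            "ndvi_valid": g.ndvi_valid.astype(int),
            "cohvv_valid": g.cohvv_valid.astype(int),
            "cohvh_valid": g.cohvh_valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.8g")
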