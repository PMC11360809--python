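"""Lloret tree-resilience indices and their aggregation.

For an event year Dr and a window of w years (default 3):

* resistance  Res = Dr / preDr          (growth kept during the event)
* recovery    Rec = postDr / Dr         (rebound after the event)
* resilience  Rsl = postDr / preDr      (return to pre-event growth)
* relative resilience relRsl = (postDr - Dr) / preDr = Rsl - Res

with preDr and postDr the mean ring widths of the w years before and
after the event.  Indices are computed on raw ring width.  When two
event years are closer than 2w+1 years, their pre/post windows overlap
another event and the records are flagged as window-contaminated (the
values are reported as-is, never corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ringwidth_io import RingSeries, SeriesCollection

DEFAULT_WINDOW = 3

INDEX_COLUMNS = ["resistance", "recovery", "resilience", "relative_resilience"]


class WindowError(ValueError):
    """The series does not fully cover the event window."""


@dataclass
class ResilienceRecord:
    """The four indices plus the underlying window means for one tree and event."""

    series_id: str
    event_year: int
    pre_dr: float
    dr: float
    post_dr: float
    resistance: float
    recovery: float
    resilience: float
    relative_resilience: float
    contaminated: bool = False


def lloret_indices(series: RingSeries, event_year: int,
                   window: int = DEFAULT_WINDOW) -> ResilienceRecord:
    """Compute the Lloret indices for one tree and event year.

    Raises :class:`WindowError` when the series does not cover
    [event - window, event + window] completely.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if series.first_year > event_year - window or series.last_year < event_year + window:
        raise WindowError(
            f"series {series.series_id!r} does not cover "
            f"[{event_year - window}, {event_year + window}]")
    i = event_year - series.first_year
    pre = float(series.rw[i - window:i].mean())
    dr = float(series.rw[i])
    post = float(series.rw[i + 1:i + 1 + window].mean())
    return ResilienceRecord(
        series_id=series.series_id, event_year=event_year,
        pre_dr=pre, dr=dr, post_dr=post,
        resistance=dr / pre, recovery=post / dr, resilience=post / pre,
        relative_resilience=(post - dr) / pre)


def contaminated_events(event_years, window: int = DEFAULT_WINDOW) -> set[int]:
    """Event years whose pre/post windows overlap another event year."""
    events = sorted(set(int(e) for e in event_years))
    bad = set()
    for a in events:
        for b in events:
            if a != b and abs(a - b) < 2 * window + 1:
                bad.add(a)
    return bad


def compute_collection(collection: SeriesCollection, event_years,
                       window: int = DEFAULT_WINDOW) -> tuple[pd.DataFrame, int]:
    """Indices for every tree and event year, with contamination flags.

    Trees not covering an event window are skipped and counted (second
    return value), never imputed.  The frame carries the provenance,
    block and site labels of each tree for downstream grouping.
    """
    contaminated = contaminated_events(event_years, window)
    rows, skipped = [], 0
    for event in sorted(set(int(e) for e in event_years)):
        for s in collection:
            try:
                rec = lloret_indices(s, event, window)
            except WindowError:
                skipped += 1
                continue
            rec.contaminated = event in contaminated
            row = vars(rec).copy()
            row.update(provenance_id=s.provenance_id, block_id=s.block_id,
                       site_id=s.site_id)
            rows.append(row)
    return pd.DataFrame(rows), skipped


def aggregate(records: pd.DataFrame, by: str = "provenance_id") -> pd.DataFrame:
    """Mean, SD and n of each index per group (and per event year).

    ``by`` is typically ``provenance_id`` or ``site_id``; means are over
    trees, not over block means.
    """
    if records.empty:
        raise ValueError("no resilience records to aggregate")
    out = (records.groupby([by, "event_year"])[INDEX_COLUMNS]
           .agg(["mean", "std", "count"]))
    out.columns = [f"{idx}_{stat}" for idx, stat in out.columns]
    for idx in INDEX_COLUMNS:  # single-record groups have no spread, not NaN
        col = f"{idx}_std"
        out[col] = out[col].fillna(0.0)
    return out.reset_index()


def percent_difference(a: float, b: float) -> float:
    """Percent difference 100 (a - b) / b of two group means (requires b > 0)."""
    if b <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (a - b) / b
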