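"""Ring-width series containers, Tucson (RWL) I/O, screening and collection statistics.

A :class:`RingSeries` is one tree's dated annual record of total ring width
(RW), optionally split into earlywood (EW) and latewood (LW), all in mm.
A :class:`SeriesCollection` groups the cores of one trial site.  Screening
follows common dendrochronological practice: each series is correlated with
the mean of all other series (the leave-one-out master) after high-pass
filtering, and series whose intercorrelation falls below a threshold
(default 0.328) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: tolerance for the additivity check |EW + LW - RW| (mm)
MEASUREMENT_TOL_MM = 0.01

#: default screening threshold for series intercorrelation
DEFAULT_INTERCORRELATION_THRESHOLD = 0.328

#: minimum overlap (years) for any correlation between series
MIN_OVERLAP_YEARS = 10


class RingDataError(ValueError):
    """Invalid ring-width data (gaps, non-positive rings, inconsistent EW/LW)."""


class RwlParseError(ValueError):
    """Malformed Tucson/RWL input; message names the offending line."""


class InsufficientOverlapError(ValueError):
    """A correlation was requested over fewer than the minimum common years."""


class EmptyCollectionError(ValueError):
    """An operation produced or received a collection with no series."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RingSeries:
    """One tree's dated annual ring record.

    Years run consecutively from ``first_year``; internal gaps (missing
    rings) are rejected.  Where both EW and LW are present they must add
    up to RW within :data:`MEASUREMENT_TOL_MM`.
    """

    series_id: str
    first_year: int
    rw: np.ndarray
    ew: np.ndarray | None = None
    lw: np.ndarray | None = None
    tree_id: str = ""
    provenance_id: str = ""
    block_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        self.rw = np.asarray(self.rw, dtype=float)
        if self.rw.ndim != 1 or self.rw.size == 0:
            raise RingDataError(f"series {self.series_id!r}: rw must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.rw)):
            raise RingDataError(
                f"series {self.series_id!r}: missing rings (gaps) are not supported"
            )
        if np.any(self.rw <= 0):
            raise RingDataError(f"series {self.series_id!r}: ring widths must be positive")
        for name in ("ew", "lw"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.rw.shape:
                    raise RingDataError(
                        f"series {self.series_id!r}: {name} length differs from rw"
                    )
                setattr(self, name, v)
        if self.ew is not None and self.lw is not None:
            err = np.abs(self.ew + self.lw - self.rw)
            if np.any(err > MEASUREMENT_TOL_MM + 1e-12):
                year = self.first_year + int(np.argmax(err))
                raise RingDataError(
                    f"series {self.series_id!r}: EW + LW != RW beyond tolerance in {year}"
                )

    def __len__(self) -> int:
        return self.rw.size

    @property
    def last_year(self) -> int:
        return self.first_year + self.rw.size - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.rw.size)

    @property
    def lwp(self) -> np.ndarray | None:
        """Latewood percentage per year (100*LW/RW), or None when LW is absent."""
        if self.lw is None:
            return None
        return latewood_percentage(self.lw, self.rw)


@dataclass
class SeriesCollection:
    """The dated ring series of one trial site."""

    series: list[RingSeries] = field(default_factory=list)
    site_id: str = ""

    def __post_init__(self) -> None:
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RingDataError(f"duplicate series id(s): {', '.join(dup)}")
        sites = {s.site_id for s in self.series if s.site_id}
        if len(sites) > 1:
            raise RingDataError(f"series from multiple sites in one collection: {sorted(sites)}")
        if not self.site_id and sites:
            self.site_id = sites.pop()

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def ids(self) -> list[str]:
        return [s.series_id for s in self.series]

    @property
    def span(self) -> tuple[int, int]:
        if not self.series:
            raise EmptyCollectionError("empty collection has no span")
        return (min(s.first_year for s in self.series),
                max(s.last_year for s in self.series))

    def get(self, series_id: str) -> RingSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)

    def to_frame(self, attr: str = "rw") -> pd.DataFrame:
        """Year-by-series matrix of ``attr`` values (NaN outside each series)."""
        cols = {}
        for s in self.series:
            v = getattr(s, attr)
            if v is None:
                continue
            cols[s.series_id] = pd.Series(v, index=s.years)
        return pd.DataFrame(cols).sort_index()


# ---------------------------------------------------------------------------
# Tucson / RWL format
# ---------------------------------------------------------------------------

def read_rwl(path) -> SeriesCollection:
    """Read a decadal Tucson (.rwl) file.

    Both common dialects are accepted: terminator ``999`` with values in
    units of 0.01 mm, and terminator ``-9999`` with values in 0.001 mm.
    Values are returned in mm; the terminator is consumed, not stored.
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            tokens = raw.split()
            if len(tokens) < 3:
                raise RwlParseError(f"line {lineno}: expected id, year and values")
            sid = tokens[0]
            try:
                year = int(tokens[1])
                values = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise RwlParseError(f"line {lineno}: non-numeric field ({exc})") from None
            if sid != current:
                if sid in groups:
                    raise RwlParseError(f"line {lineno}: duplicate series id {sid!r}")
                groups[sid] = {"first_year": year, "values": [], "expected": year}
                order.append(sid)
                current = sid
            g = groups[sid]
            if year != g["expected"]:
                raise RwlParseError(
                    f"line {lineno}: decade year {year} does not follow from "
                    f"previous lines (expected {g['expected']})"
                )
            g["values"].extend(values)
            g["expected"] = g["first_year"] + len(g["values"])

    out = []
    for sid in order:
        g = groups[sid]
        values = g["values"]
        if not values:
            raise RwlParseError(f"series {sid!r}: no values")
        if values[-1] == 999:
            divisor = 100.0
        elif values[-1] == -9999:
            divisor = 1000.0
        else:
            raise RwlParseError(f"series {sid!r}: missing terminator (999 or -9999)")
        rw = np.asarray(values[:-1], dtype=float) / divisor
        out.append(RingSeries(series_id=sid, first_year=g["first_year"], rw=rw))
    return SeriesCollection(series=out)


def write_rwl(collection: SeriesCollection, path) -> None:
    """Write a Tucson file in the 999-terminated, 0.01 mm dialect."""
    lines: list[str] = []
    for s in collection:
        if len(s.series_id) > 8:
            raise RwlParseError(f"series id {s.series_id!r} exceeds 8 characters")
        if s.first_year < -999 or s.last_year > 9999:
            raise RwlParseError(
                f"series {s.series_id!r}: span {s.first_year}-{s.last_year} not "
                "representable in the 4-character year field"
            )
        values = np.rint(s.rw * 100).astype(int)
        if np.any(values >= 99999):
            raise RwlParseError(f"series {s.series_id!r}: value too wide for Tucson field")
        tokens = [int(v) for v in values] + [999]
        year = s.first_year
        i = 0
        while i < len(tokens):
            # each line runs to the end of its decade
            n_on_line = 10 - (year % 10)
            chunk = tokens[i:i + n_on_line]
            lines.append(f"{s.series_id:<8}{year:>4}" +
                         "".join(f"{v:>6d}" for v in chunk))
            i += len(chunk)
            year += len(chunk)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# long-form table
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["site_id", "block_id", "provenance_id", "tree_id", "year",
                "rw_mm", "ew_mm", "lw_mm"]


def read_long_csv(path) -> dict[str, SeriesCollection]:
    """Read the long-form delimited table into one collection per site.

    Expected columns: site_id, block_id, provenance_id, tree_id, year,
    rw_mm and (optionally populated) ew_mm, lw_mm.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "block_id": str,
                                  "provenance_id": str, "tree_id": str})
    missing = [c for c in LONG_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise RingDataError(f"long-form table missing columns: {missing}")
    out: dict[str, SeriesCollection] = {}
    for site, site_df in df.groupby("site_id", sort=True):
        series = []
        for tree, tree_df in site_df.groupby("tree_id", sort=True):
            tree_df = tree_df.sort_values("year")
            years = tree_df["year"].to_numpy()
            if years.size > 1 and not np.all(np.diff(years) == 1):
                raise RingDataError(f"tree {tree!r}: years are not consecutive")
            ew = tree_df["ew_mm"].to_numpy(float) if "ew_mm" in tree_df else None
            lw = tree_df["lw_mm"].to_numpy(float) if "lw_mm" in tree_df else None
            if ew is not None and np.all(np.isnan(ew)):
                ew = None
            if lw is not None and np.all(np.isnan(lw)):
                lw = None
            series.append(RingSeries(
                series_id=str(tree), tree_id=str(tree),
                provenance_id=str(tree_df["provenance_id"].iloc[0]),
                block_id=str(tree_df["block_id"].iloc[0]), site_id=str(site),
                first_year=int(years[0]), rw=tree_df["rw_mm"].to_numpy(float),
                ew=ew, lw=lw))
        out[str(site)] = SeriesCollection(series=series, site_id=str(site))
    return out


def write_long_csv(collections, path) -> None:
    """Write collections to the long-form table (inverse of :func:`read_long_csv`)."""
    if isinstance(collections, SeriesCollection):
        collections = {collections.site_id: collections}
    rows = []
    for site, coll in collections.items():
        for s in coll:
            for i, year in enumerate(s.years):
                rows.append({
                    "site_id": site, "block_id": s.block_id,
                    "provenance_id": s.provenance_id, "tree_id": s.tree_id or s.series_id,
                    "year": int(year), "rw_mm": s.rw[i],
                    "ew_mm": s.ew[i] if s.ew is not None else np.nan,
                    "lw_mm": s.lw[i] if s.lw is not None else np.nan,
                })
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived quantities and screening
# ---------------------------------------------------------------------------

def latewood_percentage(lw, rw):
    """Latewood share of the ring, 100*LW/RW (percent).

    Accepts scalars or arrays; requires RW > 0 and 0 <= LW <= RW.
    """
    lw_a = np.asarray(lw, dtype=float)
    rw_a = np.asarray(rw, dtype=float)
    if np.any(rw_a <= 0):
        raise RingDataError("latewood_percentage: RW must be positive")
    if np.any(lw_a < 0) or np.any(lw_a > rw_a):
        raise RingDataError("latewood_percentage: LW must lie in [0, RW]")
    out = 100.0 * lw_a / rw_a
    if np.isscalar(lw) and np.isscalar(rw):
        return float(out)
    return out


def _highpass(series: RingSeries) -> pd.Series:
    # first difference of log ring width, indexed by the later year
    d = np.diff(np.log(series.rw))
    return pd.Series(d, index=series.years[1:])


def series_intercorrelation(collection: SeriesCollection, target: str,
                            min_overlap: int = MIN_OVERLAP_YEARS) -> float:
    """Correlation of one series with the leave-one-out master chronology.

    Series are high-pass filtered (first difference of log values) before
    correlating, so the statistic measures shared year-to-year signal
    rather than the common age trend.  The master is the per-year mean of
    the filtered values of all other series.
    """
    tgt = _highpass(collection.get(target))
    others = [_highpass(s) for s in collection if s.series_id != target]
    if not others:
        raise InsufficientOverlapError(
            f"series {target!r}: no other series to build a master from")
    master = pd.concat(others, axis=1).mean(axis=1)
    common = tgt.index.intersection(master.dropna().index)
    if len(common) < min_overlap:
        raise InsufficientOverlapError(
            f"series {target!r}: only {len(common)} years overlap with the master "
            f"(minimum {min_overlap})")
    a = tgt.loc[common].to_numpy()
    b = master.loc[common].to_numpy()
    return float(np.corrcoef(a, b)[0, 1])


def screen_collection(collection: SeriesCollection,
                      threshold: float = DEFAULT_INTERCORRELATION_THRESHOLD,
                      min_overlap: int = MIN_OVERLAP_YEARS,
                      ) -> tuple[SeriesCollection, list[str]]:
    """One-pass screening: drop series whose intercorrelation is below ``threshold``.

    Series whose overlap with the master is too short to assess are
    rejected explicitly rather than silently retained.  Returns the
    retained collection and the rejected series ids.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    retained, rejected = [], []
    for s in collection:
        try:
            r = series_intercorrelation(collection, s.series_id, min_overlap)
        except InsufficientOverlapError:
            rejected.append(s.series_id)
            continue
        if threshold == 0 or r >= threshold:
            retained.append(s)
        else:
            rejected.append(s.series_id)
    if not retained:
        raise EmptyCollectionError(
            f"screening at threshold {threshold} rejected every series")
    return SeriesCollection(series=retained, site_id=collection.site_id), rejected


def rbar(collection: SeriesCollection, min_overlap: int = MIN_OVERLAP_YEARS) -> float:
    """Mean pairwise Pearson correlation among the ring series.

    Each pair is correlated over its common years; pairs with fewer than
    ``min_overlap`` common years are skipped.
    """
    if len(collection) < 2:
        raise EmptyCollectionError("rbar needs at least two series")
    frame = collection.to_frame("rw")
    cols = frame.columns
    rs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = frame[[cols[i], cols[j]]].dropna()
            if len(pair) < min_overlap:
                continue
            rs.append(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
    if not rs:
        raise InsufficientOverlapError("no series pair with sufficient overlap")
    return float(np.mean(rs))
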