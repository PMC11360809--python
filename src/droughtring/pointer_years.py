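"""Pointer-year detection from relative growth change.

A year is a negative (positive) pointer year when at least a given
fraction of the trees covering it — default 60% — show a relative
growth change beyond a per-tree magnitude threshold (default 10%),
in the spirit of the Becker interval-trend method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ringwidth_io import RingSeries, SeriesCollection

logger = logging.getLogger(__name__)

MIN_TREES_PER_YEAR = 5


@dataclass
class PointerResult:
    """Per-year pointer classification.

    ``nature`` is -1 (negative pointer year), +1 (positive) or 0.
    """

    year: int
    nature: int
    fraction_decreasing: float
    fraction_increasing: float
    n_trees: int


def relative_growth_change(series: RingSeries) -> pd.Series:
    """Percent growth change RGC(t) = 100 (rw_t - rw_{t-1}) / rw_{t-1}.

    Indexed by year; the first year of the series is undefined and omitted.
    """
    if len(series) < 2:
        raise ValueError(f"series {series.series_id!r}: need at least 2 years")
    rw = series.rw
    rgc = 100.0 * (rw[1:] - rw[:-1]) / rw[:-1]
    return pd.Series(rgc, index=series.years[1:])


def pointer_years(collection: SeriesCollection, tree_fraction: float = 0.60,
                  rgc_threshold: float = 10.0,
                  min_trees: int = MIN_TREES_PER_YEAR) -> list[PointerResult]:
    """Detect pointer years across a collection.

    A tree is influenced negatively in year t when RGC(t) <= -rgc_threshold
    (positively when >= +rgc_threshold); the year's nature follows from the
    fraction of influenced trees.  Years covered by fewer than ``min_trees``
    trees are skipped with a log notice.
    """
    if not 0 < tree_fraction <= 1:
        raise ValueError("tree_fraction must lie in (0, 1]")
    rgc = pd.DataFrame({s.series_id: relative_growth_change(s) for s in collection})
    results = []
    for year, row in rgc.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size < min_trees:
            logger.info("year %d skipped: only %d trees (< %d)", year, vals.size, min_trees)
            continue
        f_dec = float(np.mean(vals <= -rgc_threshold))
        f_inc = float(np.mean(vals >= rgc_threshold))
        if f_dec >= tree_fraction and f_inc >= tree_fraction:
            # only possible for tree_fraction <= 0.5; tie resolved to no pointer
            nature = 0 if f_dec == f_inc else (-1 if f_dec > f_inc else 1)
        elif f_dec >= tree_fraction:
            nature = -1
        elif f_inc >= tree_fraction:
            nature = 1
        else:
            nature = 0
        results.append(PointerResult(year=int(year), nature=nature,
                                     fraction_decreasing=f_dec,
                                     fraction_increasing=f_inc,
                                     n_trees=int(vals.size)))
    return results


def pointer_table(results: list[PointerResult]) -> pd.DataFrame:
    """Tabular form: year, nature, fractions, n_trees."""
    return pd.DataFrame([vars(r) for r in results])
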