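"""Moving-window correlation and response functions between chronology and climate.

For each sliding subperiod (default 25 years) the chronology is related
to monthly temperature and precipitation of the growing season (default
March-September, 14 predictors).  The correlation function is the
Pearson correlation per predictor; the response function is a
principal-components regression: predictors are standardized within the
window, components with eigenvalue > 1 retained, the chronology
regressed on the scores, and the coefficients rotated back to the
predictor basis.  Significance of both is assessed by bootstrap
resampling of years within the window (percentile 95% interval
excluding zero).  All randomness is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_drought import ClimateSeries
from .detrend_chronology import Chronology

DEFAULT_MONTHS = tuple(range(3, 10))  # March-September
DEFAULT_WINDOW_LENGTH = 25
DEFAULT_N_BOOT = 1000

_MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]


class CoverageError(ValueError):
    """Chronology or climate does not cover the requested window."""


@dataclass
class WindowResult:
    """Coefficients and significance flags of one subperiod.

    ``table`` has one row per predictor: variable, month, kind (T/P),
    correlation, corr_significant, response, resp_significant.
    """

    start: int
    end: int
    table: pd.DataFrame


def sliding_windows(start: int, end: int, length: int = DEFAULT_WINDOW_LENGTH,
                    step: int = 1) -> list[tuple[int, int]]:
    """All [s, s+length-1] windows inside [start, end]; count = span - length + 1."""
    span = end - start + 1
    if span < length:
        raise ValueError(f"span {span} shorter than window length {length}")
    return [(s, s + length - 1) for s in range(start, end - length + 2, step)]


def predictor_names(months=DEFAULT_MONTHS) -> list[str]:
    return [f"{kind}_{_MONTH_ABBR[m - 1]}" for kind in ("T", "P") for m in months]


def climate_matrix(climate: ClimateSeries, years, months=DEFAULT_MONTHS) -> pd.DataFrame:
    """Year-by-predictor matrix of monthly T and P for the given months."""
    years = np.asarray(years, dtype=int)
    cols = {}
    for kind, column in (("T", "tmean"), ("P", "prec")):
        pivot = climate.monthly(column)
        for m in months:
            name = f"{kind}_{_MONTH_ABBR[m - 1]}"
            cols[name] = pivot[m]
    mat = pd.DataFrame(cols).reindex(years)
    if mat.isna().any().any():
        missing = mat.index[mat.isna().any(axis=1)].tolist()
        raise CoverageError(f"climate missing for years {missing}")
    return mat


def _chronology_values(chron: Chronology, years: np.ndarray) -> np.ndarray:
    s = chron.as_series().reindex(years)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise CoverageError(f"chronology missing for years {missing}")
    return s.to_numpy()


def _boot_indices(rng: np.random.Generator, n_boot: int, n: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def _bootstrap_correlations(y: np.ndarray, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson r per predictor for each bootstrap resample (vectorized)."""
    yb = y[idx]                      # (B, n)
    xb = x[idx]                      # (B, n, p)
    yc = yb - yb.mean(axis=1, keepdims=True)
    xc = xb - xb.mean(axis=1, keepdims=True)
    num = np.einsum("bn,bnp->bp", yc, xc)
    den = (np.sqrt(np.einsum("bn,bn->b", yc, yc))[:, None]
           * np.sqrt(np.einsum("bnp,bnp->bp", xc, xc)))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _pcr_coefficients(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Back-rotated PCR coefficients; components with eigenvalue > 1 retained."""
    n = y.size
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    corr = xs.T @ xs / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    keep = eigval > 1.0
    if not keep.any():
        raise ValueError("no principal component with eigenvalue > 1")
    v = eigvec[:, keep]
    scores = xs @ v
    beta, *_ = np.linalg.lstsq(scores, ys, rcond=None)
    return v @ beta


def correlation_function(chron: Chronology, climate: ClimateSeries,
                         window: tuple[int, int], months=DEFAULT_MONTHS,
                         n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                         rng: np.random.Generator | None = None) -> WindowResult:
    """Correlation part of the climate-growth function for one window."""
    start, end = window
    years = np.arange(start, end + 1)
    y = _chronology_values(chron, years)
    mat = climate_matrix(climate, years, months)
    x = mat.to_numpy()
    r = _bootstrap_correlations(y, x, np.arange(y.size)[None, :])[0]
    rng = rng if rng is not None else np.random.default_rng(seed)
    rb = _bootstrap_correlations(y, x, _boot_indices(rng, n_boot, y.size))
    lo, hi = np.nanpercentile(rb, [2.5, 97.5], axis=0)
    sig = (lo > 0) | (hi < 0)
    table = _make_table(mat.columns, months, correlation=r, corr_significant=sig)
    return WindowResult(start=start, end=end, table=table)


def response_function(chron: Chronology, climate: ClimateSeries,
                      window: tuple[int, int], months=DEFAULT_MONTHS,
                      n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> WindowResult:
    """Response (PCR) part of the climate-growth function for one window."""
    start, end = window
    years = np.arange(start, end + 1)
    y = _chronology_values(chron, years)
    mat = climate_matrix(climate, years, months)
    x = mat.to_numpy()
    coef = _pcr_coefficients(y, x)
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = _boot_indices(rng, n_boot, y.size)
    boot = np.full((n_boot, x.shape[1]), np.nan)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if yb.std(ddof=1) == 0 or np.any(xb.std(axis=0, ddof=1) == 0):
            continue
        try:
            boot[b] = _pcr_coefficients(yb, xb)
        except ValueError:
            continue
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    sig = (lo > 0) | (hi < 0)
    table = _make_table(mat.columns, months, response=coef, resp_significant=sig)
    return WindowResult(start=start, end=end, table=table)


def _make_table(names, months, **cols) -> pd.DataFrame:
    months = list(months)
    base = pd.DataFrame({
        "variable": list(names),
        "kind": [n.split("_")[0] for n in names],
        "month": months + months,
    })
    for k, v in cols.items():
        base[k] = v
    return base


def climate_growth_windows(chron: Chronology, climate: ClimateSeries,
                           start: int, end: int,
                           length: int = DEFAULT_WINDOW_LENGTH,
                           months=DEFAULT_MONTHS, n_boot: int = DEFAULT_N_BOOT,
                           seed: int = 0) -> list[WindowResult]:
    """Correlation and response functions over all sliding windows.

    One RNG, seeded once, drives every bootstrap so the whole set of
    windows is reproducible bit-for-bit under the same seed.
    """
    rng = np.random.default_rng(seed)
    results = []
    for window in sliding_windows(start, end, length):
        c = correlation_function(chron, climate, window, months, n_boot, rng=rng)
        r = response_function(chron, climate, window, months, n_boot, rng=rng)
        table = c.table.merge(r.table, on=["variable", "kind", "month"])
        results.append(WindowResult(start=window[0], end=window[1], table=table))
    return results


def windows_table(results: list[WindowResult]) -> pd.DataFrame:
    """Long-form table of all windows (the tabular twin of the moving plots)."""
    frames = []
    for res in results:
        t = res.table.copy()
        t.insert(0, "window_start", res.start)
        t.insert(1, "window_end", res.end)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def nonstationarity_profile(results: list[WindowResult], variable: str,
                            kind: str = "correlation") -> pd.DataFrame:
    """Coefficient trajectory of one predictor across windows with change flags.

    ``kind`` selects the correlation or the response coefficient; the
    significance flag of the same kind is tracked.  Rows are annotated
    with sign changes and significance changes relative to the previous
    window; a single window yields no annotations.
    """
    if len(results) < 1:
        raise ValueError("need at least one window result")
    coef_col = "correlation" if kind == "correlation" else "response"
    sig_col = "corr_significant" if kind == "correlation" else "resp_significant"
    rows = []
    for res in results:
        t = res.table
        sel = t[t["variable"] == variable]
        if sel.empty:
            raise KeyError(f"variable {variable!r} absent from window result")
        if coef_col not in sel.columns:
            raise KeyError(f"{coef_col!r} not computed for these windows")
        rows.append({"window_start": res.start, "window_end": res.end,
                     "coefficient": float(sel[coef_col].iloc[0]),
                     "significant": bool(sel[sig_col].iloc[0])})
    out = pd.DataFrame(rows)
    coef = out["coefficient"].to_numpy()
    sig = out["significant"].to_numpy()
    sign_change = np.zeros(len(out), dtype=bool)
    sig_change = np.zeros(len(out), dtype=bool)
    if len(out) > 1:
        sign_change[1:] = np.sign(coef[1:]) != np.sign(coef[:-1])
        sig_change[1:] = sig[1:] != sig[:-1]
    out["sign_change"] = sign_change
    out["significance_change"] = sig_change
    return out
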