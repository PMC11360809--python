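"""Synthetic climate and multi-provenance ring-width data with known ground truth.

The generator emulates a Carpathian Norway spruce provenance trial:
seasonal monthly climate with a warming trend and imposed drought
years, and a randomised complete block design of provenances whose
ring widths follow a negative-exponential age curve modulated, on the
log scale, by provenance effects, block effects, a summer water-balance
signal shared by all trees of a site, per-provenance drought-year
growth reductions, and lognormal noise.  The multiplicative (log-scale)
model gives the resilience indices closed-form expectations under the
generator: a drought year with imposed reduction d has expected
resistance ~ (1 - d).

Also provided are loaders for the packaged transcription of the
published drought calendar of the three Romanian trials (Dorna
Candrenilor, Turda, Zarnesti) and of their printed summary statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .climate_drought import ClimateSeries, DroughtCalendar, thornthwaite_pet
from .ringwidth_io import RingSeries, SeriesCollection

# Carpathian montane monthly normals (deg C / mm), roughly MAT 5.5, AP 700 mm
DEFAULT_T_NORMALS = (-5.0, -4.0, 0.0, 6.0, 11.0, 14.0, 16.0, 15.5, 11.0, 6.0, 1.0, -3.0)
DEFAULT_P_NORMALS = (30.0, 30.0, 35.0, 55.0, 85.0, 110.0, 100.0, 80.0, 55.0, 45.0, 35.0, 30.0)

_TABLE1_SHA256 = "941867bcdd2c236328543a79b7fe9753efa6e2d4b0ef86abd144e3f853a6b1ed"
_SUMMARY_SHA256 = "db8b4d8c6ed3c36bde1d03da6192e0da1e7a89780f5b5b0607f6f2f19a0af8cb"


class FixtureError(RuntimeError):
    """A packaged fixture is missing or fails its checksum."""


@dataclass(frozen=True)
class DroughtEvent:
    """An imposed drought: precipitation deficit and growth reduction in one year."""

    year: int
    months: tuple = (6, 7, 8)
    precip_deficit: float = 0.6    # fraction of normal precipitation removed
    growth_reduction: float = 0.4  # fractional ring-width reduction in that year


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trial site.

    Defaults mirror the analysed trials: three blocks, 81 provenances
    with four cored trees per plot, span 1972-2020 (49 years, enough for
    25-year moving windows), a 0.4 deg C/decade warming trend, and
    extreme droughts in 2000 and 2003 imposed jointly on precipitation
    and growth.
    """

    seed: int = 0
    start_year: int = 1972
    end_year: int = 2020
    site_id: str = "SIM"
    latitude: float = 47.0
    t_normals: tuple = DEFAULT_T_NORMALS
    p_normals: tuple = DEFAULT_P_NORMALS
    t_trend_per_decade: float = 0.4
    t_noise_sd: float = 0.7
    p_gamma_shape: float = 9.0
    # the 2000 event runs June-December, matching the published drought
    # calendar for that year, which also made 2000 the driest year on
    # record at every trial site
    droughts: tuple = (DroughtEvent(2000, (6, 7, 8, 9, 10, 11, 12), 0.6, 0.40),
                       DroughtEvent(2003, (5, 6, 7, 8), 0.6, 0.30))
    n_provenances: int = 81
    n_blocks: int = 3
    trees_per_plot: int = 4
    provenance_sd: float = 0.10
    block_sd: float = 0.05
    ring_noise_sd: float = 0.10
    drought_sensitivity_sd: float = 0.2
    beta_climate: float = 0.15
    age_curve_a: float = 2.5   # mm, amplitude of the juvenile surge
    age_curve_b: float = 0.05  # 1/yr, decay rate
    age_curve_k: float = 1.6   # mm, mature asymptote
    lwp_base: float = 0.28
    lwp_climate: float = 0.04
    lwp_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.end_year - self.start_year + 1 < 35:
            raise ValueError("span must be >= 35 years (25-year windows need room)")
        for name in ("t_noise_sd", "provenance_sd", "block_sd", "ring_noise_sd",
                     "drought_sensitivity_sd", "lwp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trees_per_plot < 1:
            raise ValueError("trees_per_plot must be >= 1")
        if any(p < 0 for p in self.p_normals):
            raise ValueError("precipitation normals must be >= 0")
        if len(self.t_normals) != 12 or len(self.p_normals) != 12:
            raise ValueError("normals must have 12 monthly values")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


@dataclass
class GroundTruth:
    """Everything the generator imposed, for recovery checks."""

    provenance_effects: np.ndarray      # log-scale, one per provenance
    block_effects: np.ndarray           # log-scale, one per block
    drought_sensitivities: np.ndarray   # multiplier on the imposed reduction
    drought_reductions: dict            # year -> fractional growth reduction
    beta_climate: float
    provenance_coords: pd.DataFrame = field(default_factory=pd.DataFrame)


def gen_climate(config: SimulationConfig,
                rng: np.random.Generator | None = None) -> ClimateSeries:
    """Monthly climate: seasonal normals + warming trend + noise; gamma rainfall.

    Drought events remove the stated fraction of precipitation in their
    months.  Deterministic under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    years = config.years
    t_norm = np.asarray(config.t_normals)
    p_norm = np.asarray(config.p_normals)
    rows = []
    deficits = {(e.year, m): e.precip_deficit for e in config.droughts for m in e.months}
    for year in years:
        decades = (year - config.start_year) / 10.0
        t = (t_norm + config.t_trend_per_decade * decades
             + rng.normal(0, config.t_noise_sd, 12))
        shape = config.p_gamma_shape
        p = np.where(p_norm > 0,
                     rng.gamma(shape, np.maximum(p_norm, 1e-9) / shape, 12), 0.0)
        for m in range(1, 13):
            deficit = deficits.get((int(year), m), 0.0)
            rows.append({"year": int(year), "month": m, "tmean": t[m - 1],
                         "prec": p[m - 1] * (1.0 - deficit)})
    return ClimateSeries(site_id=config.site_id, latitude=config.latitude,
                         data=pd.DataFrame(rows))


def _summer_balance_z(climate: ClimateSeries) -> pd.Series:
    """Z-scored June-August water balance per year (the shared growth signal)."""
    if "balance" not in climate.data.columns:
        climate = thornthwaite_pet(climate)
    summer = climate.data[climate.data["month"].isin([6, 7, 8])]
    bal = summer.groupby("year")["balance"].sum()
    return (bal - bal.mean()) / bal.std(ddof=1)


def _late_season_dryness_z(climate: ClimateSeries) -> pd.Series:
    """Z-scored July-September precipitation shortfall (drives latewood share)."""
    late = climate.data[climate.data["month"].isin([7, 8, 9])]
    p = late.groupby("year")["prec"].sum()
    return -(p - p.mean()) / p.std(ddof=1)


def gen_rings(config: SimulationConfig, climate: ClimateSeries,
              rng: np.random.Generator | None = None,
              ) -> tuple[SeriesCollection, GroundTruth]:
    """Ring series for every tree of the design, plus the imposed ground truth.

    log RW(tree, year) = log age_curve(age) + provenance + block
                         + beta * summer-balance z + log(1 - d * sensitivity)
                         + N(0, ring_noise_sd)

    EW/LW are split by a latewood fraction that increases with
    late-season dryness; EW + LW = RW exactly.
    """
    if (int(climate.years[0]) > config.start_year
            or int(climate.years[-1]) < config.end_year):
        raise ValueError("climate does not cover the simulation span")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    years = config.years
    n_y = config.n_years

    z = _summer_balance_z(climate).reindex(years).to_numpy()
    z_late = _late_season_dryness_z(climate).reindex(years).to_numpy()

    p_eff = rng.normal(0, config.provenance_sd, config.n_provenances)
    b_eff = rng.normal(0, config.block_sd, config.n_blocks)
    sens = np.clip(rng.normal(1.0, config.drought_sensitivity_sd,
                              config.n_provenances), 0.0, None)
    reductions = {e.year: e.growth_reduction for e in config.droughts}

    coords = pd.DataFrame({
        "provenance_id": [f"{j + 1:02d}" for j in range(config.n_provenances)],
        "latitude": rng.uniform(46.0, 62.0, config.n_provenances),
        "longitude": rng.uniform(5.0, 28.0, config.n_provenances),
        "elevation": rng.uniform(300.0, 1500.0, config.n_provenances),
    })

    age = np.arange(1, n_y + 1)
    curve = config.age_curve_a * np.exp(-config.age_curve_b * age) + config.age_curve_k
    log_curve = np.log(curve)

    drought_log = np.zeros((config.n_provenances, n_y))
    for e in config.droughts:
        iy = int(e.year - config.start_year)
        if 0 <= iy < n_y:
            drought_log[:, iy] += np.log(np.clip(1.0 - e.growth_reduction * sens,
                                                 0.05, None))

    series = []
    for j in range(config.n_provenances):
        for k in range(config.n_blocks):
            for t in range(config.trees_per_plot):
                noise = rng.normal(0, config.ring_noise_sd, n_y)
                log_rw = (log_curve + p_eff[j] + b_eff[k]
                          + config.beta_climate * z + drought_log[j] + noise)
                rw = np.exp(log_rw)
                frac = np.clip(config.lwp_base + config.lwp_climate * z_late
                               + rng.normal(0, config.lwp_noise_sd, n_y), 0.05, 0.60)
                lw = rw * frac
                sid = f"P{j + 1:02d}B{k + 1}T{t + 1}"
                series.append(RingSeries(
                    series_id=sid, tree_id=sid,
                    provenance_id=f"{j + 1:02d}", block_id=str(k + 1),
                    site_id=config.site_id, first_year=config.start_year,
                    rw=rw, ew=rw - lw, lw=lw))
    truth = GroundTruth(provenance_effects=p_eff, block_effects=b_eff,
                        drought_sensitivities=sens, drought_reductions=reductions,
                        beta_climate=config.beta_climate, provenance_coords=coords)
    return SeriesCollection(series=series, site_id=config.site_id), truth


# ---------------------------------------------------------------------------
# packaged fixtures (transcriptions of the published tables)
# ---------------------------------------------------------------------------

def _read_fixture(name: str, expected_sha: str) -> str:
    try:
        text = resources.files("droughtring.data").joinpath(name).read_text()
    except FileNotFoundError as exc:
        raise FixtureError(f"packaged fixture {name!r} is missing") from exc
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != expected_sha:
        raise FixtureError(
            f"fixture {name!r} checksum mismatch: {digest} != {expected_sha}")
    return text


def load_table1_fixture() -> dict[str, DroughtCalendar]:
    """Published drought calendars (severe/extreme months) for the three trials."""
    import io
    text = _read_fixture("table1_drought_calendar.csv", _TABLE1_SHA256)
    df = pd.read_csv(io.StringIO(text))
    out = {}
    for site, grp in df.groupby("site", sort=True):
        out[str(site)] = DroughtCalendar(
            site_id=str(site),
            entries=grp[["year", "month", "severity"]].reset_index(drop=True))
    return out


def load_summary_fixture() -> dict:
    """Published trial-level summary numbers (core counts, mean RW, rbar, indices)."""
    text = _read_fixture("trial_summary.json", _SUMMARY_SHA256)
    return json.loads(text)
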