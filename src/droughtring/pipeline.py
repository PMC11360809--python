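"""End-to-end orchestration: ingest -> screen -> detrend -> SPEI -> pointer
years -> resilience -> variation/correlation statistics -> moving windows.

A :class:`RunConfig` holds every stage parameter, each defaulting to the
published analysis settings (screening at 0.328, spline response 0.50 at
0.67 of series length, SPEI-3 with breakpoints -1/-1.5/-2, 60% pointer
threshold, 3-year resilience windows, 25-year subperiods over
March-September climate).  Event years for the resilience stage default
to the extreme-drought years common to all sites, as derived from the
computed calendars.  Every run writes a JSON manifest with all
parameters and seeds; stochastic stages refuse to run without a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate_drought import (ClimateSeries, classify_drought, drought_year_summary,
                              spei, thornthwaite_pet)
from .climate_growth import climate_growth_windows, windows_table
from .detrend_chronology import build_chronology, spline_detrend
from .pointer_years import pointer_table, pointer_years
from .resilience import aggregate, compute_collection
from .ringwidth_io import SeriesCollection, rbar, read_long_csv, screen_collection
from .synthetic_data import SimulationConfig, gen_climate, gen_rings
from .variation_stats import correlation_table, fit_variation_model

TABLE_FILES = ["calendar.csv", "series_stats.csv", "variation_tests.csv",
               "resilience_by_provenance.csv", "correlations_geo.csv",
               "correlations_traits.csv", "moving_windows.csv", "pointer_years.csv"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run."""

    out_dir: str = "run_output"
    seed: int | None = None
    # inputs: either simulation configs (one per site) or file paths
    simulations: list = field(default_factory=list)   # list[SimulationConfig]
    rings_path: str | None = None                      # long-form CSV
    climate_path: str | None = None                    # climate CSV
    site_latitudes: dict = field(default_factory=dict)
    # stage parameters (published defaults)
    screen_threshold: float = 0.328
    nyrs_frac: float = 0.67
    spline_response: float = 0.5
    spei_scale: int = 3
    drought_thresholds: tuple = (-1.0, -1.5, -2.0)
    pointer_fraction: float = 0.60
    rgc_threshold: float = 10.0
    resilience_window: int = 3
    event_years: list | None = None   # None -> common extreme years from calendars
    cg_window_length: int = 25
    cg_start: int | None = None
    cg_end: int | None = None
    cg_months: tuple = tuple(range(3, 10))
    n_boot: int = 1000
    run_climate_growth: bool = True
    run_variation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sims = [SimulationConfig(**s) for s in raw.pop("simulations", [])]
        cfg = cls(**raw)
        cfg.simulations = sims
        return cfg


def _trait_frame(collection: SeriesCollection) -> pd.DataFrame:
    rows = []
    for s in collection:
        lwp = s.lwp
        for i, year in enumerate(s.years):
            rows.append({"provenance_id": s.provenance_id, "block_id": s.block_id,
                         "tree_id": s.tree_id or s.series_id, "year": int(year),
                         "RW": s.rw[i],
                         "EW": s.ew[i] if s.ew is not None else np.nan,
                         "LW": s.lw[i] if s.lw is not None else np.nan,
                         "LWP": lwp[i] if lwp is not None else np.nan})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage and write the output tables and manifest.

    Returns the manifest.  Any stage failure raises
    :class:`PipelineError` naming the stage; tables written before the
    failure are kept and the manifest marks the run incomplete.
    """
    if config.seed is None:
        raise PipelineError("configuration: pipeline runs require an explicit seed")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if k not in ("simulations",)},
        "simulated_sites": [s.site_id for s in config.simulations],
        "stages_completed": [],
        "complete": False,
        "outputs": {},
        "notes": [],
    }

    def _write(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(out / name, index=False, float_format="%.6g")
        manifest["outputs"][name] = len(frame)

    def _manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        stage = "ingest"
        collections: dict[str, SeriesCollection] = {}
        climates: dict[str, ClimateSeries] = {}
        coords: dict[str, pd.DataFrame] = {}
        if config.simulations:
            for i, sim in enumerate(config.simulations):
                rng = np.random.default_rng(config.seed + 1000 * i)
                clim = gen_climate(sim, rng)
                coll, truth = gen_rings(sim, clim, rng)
                collections[sim.site_id] = coll
                climates[sim.site_id] = clim
                coords[sim.site_id] = truth.provenance_coords
        else:
            if not config.rings_path or not config.climate_path:
                raise PipelineError("ingest: need simulations or rings/climate paths")
            collections = read_long_csv(config.rings_path)
            clim_df = pd.read_csv(config.climate_path)
            for site, grp in clim_df.groupby("site_id"):
                lat = float(config.site_latitudes.get(str(site), 47.0))
                climates[str(site)] = ClimateSeries(
                    site_id=str(site), latitude=lat,
                    data=grp.rename(columns={"tmean_c": "tmean", "prec_mm": "prec"})
                    [["year", "month", "tmean", "prec"]])
        manifest["stages_completed"].append(stage)

        stage = "screen"
        stats_rows = []
        for site in sorted(collections):
            coll = collections[site]
            retained, rejected = screen_collection(coll, config.screen_threshold)
            stats_rows.append({
                "site": site, "n_series": len(coll), "n_retained": len(retained),
                "n_rejected": len(rejected), "rbar": rbar(retained),
                "mean_rw_mm": float(np.mean([s.rw.mean() for s in retained]))})
            collections[site] = retained
        _write("series_stats.csv", pd.DataFrame(stats_rows))
        manifest["stages_completed"].append(stage)

        stage = "detrend"
        chronologies = {}
        for site, coll in collections.items():
            indices = [spline_detrend(s, config.nyrs_frac, config.spline_response)
                       for s in coll]
            chronologies[site] = build_chronology(indices, ident=site)
        manifest["stages_completed"].append(stage)

        stage = "spei_calendar"
        calendars = {}
        cal_rows = []
        for site, clim in climates.items():
            clim = thornthwaite_pet(clim)
            climates[site] = clim
            sp = spei(clim, config.spei_scale)
            calendars[site] = classify_drought(sp, config.drought_thresholds)
            e = calendars[site].entries
            cal_rows.append(e.assign(site=site))
        _write("calendar.csv", pd.concat(cal_rows, ignore_index=True)
               [["site", "year", "month", "severity"]])
        manifest["stages_completed"].append(stage)

        stage = "pointer_years"
        ptr_rows = []
        for site, coll in collections.items():
            res = pointer_years(coll, config.pointer_fraction, config.rgc_threshold)
            ptr_rows.append(pointer_table(res).assign(site=site))
        _write("pointer_years.csv", pd.concat(ptr_rows, ignore_index=True))
        manifest["stages_completed"].append(stage)

        stage = "resilience"
        if config.event_years is not None:
            events = [int(e) for e in config.event_years]
        else:
            events = drought_year_summary(calendars.values())["common_extreme_years"]
            manifest["notes"].append(f"event years derived from calendars: {events}")
        manifest["event_years"] = events
        res_frames, record_frames = [], {}
        if events:
            for site, coll in collections.items():
                records, skipped = compute_collection(coll, events,
                                                      config.resilience_window)
                record_frames[site] = records
                if records.empty:
                    continue
                agg = aggregate(records, by="provenance_id")
                agg.insert(0, "site", site)
                res_frames.append(agg)
        if res_frames:
            _write("resilience_by_provenance.csv", pd.concat(res_frames,
                                                             ignore_index=True))
        else:
            _write("resilience_by_provenance.csv", pd.DataFrame())
            manifest["notes"].append("no common extreme years: resilience table empty")
        manifest["stages_completed"].append(stage)

        if config.run_variation:
            stage = "variation_stats"
            var_rows = []
            for site, coll in collections.items():
                traits = _trait_frame(coll)
                for trait in ("RW", "EW", "LW", "LWP"):
                    if traits[trait].isna().all():
                        continue
                    r = fit_variation_model(traits, trait)
                    var_rows.append({
                        "site": site, "trait": trait,
                        "lrt_provenance": r.lrt_provenance,
                        "stars_provenance": r.stars_provenance,
                        "lrt_prov_year": r.lrt_prov_year,
                        "stars_prov_year": r.stars_prov_year,
                        "ms_block": r.ms_block, "ms_year": r.ms_year,
                        "mean": traits[trait].mean(), "sd": traits[trait].std()})
            _write("variation_tests.csv", pd.DataFrame(var_rows))

            stage = "correlations"
            geo_frames, trait_frames = [], []
            for site, coll in collections.items():
                traits = _trait_frame(coll)
                prov_means = traits.groupby("provenance_id")[
                    ["RW", "EW", "LW", "LWP"]].mean()
                merged = prov_means
                if site in coords and not coords[site].empty:
                    merged = prov_means.merge(coords[site], on="provenance_id")
                if record_frames.get(site) is not None and not record_frames[site].empty:
                    idx_means = record_frames[site].groupby("provenance_id")[
                        ["resistance", "recovery", "resilience",
                         "relative_resilience"]].mean()
                    merged = merged.merge(idx_means, on="provenance_id")
                merged = merged.drop(columns=["provenance_id"], errors="ignore")
                if {"latitude", "longitude", "elevation"} <= set(merged.columns):
                    geo = correlation_table(
                        merged,
                        x_vars=[c for c in merged.columns
                                if c not in ("latitude", "longitude", "elevation")],
                        y_vars=["latitude", "longitude", "elevation"])
                    geo.insert(0, "site", site)
                    geo_frames.append(geo)
                idx_cols = [c for c in ("resistance", "recovery", "resilience",
                                        "relative_resilience") if c in merged.columns]
                if idx_cols:
                    tc = correlation_table(merged, x_vars=["RW", "EW", "LW", "LWP"],
                                           y_vars=idx_cols)
                    tc.insert(0, "site", site)
                    trait_frames.append(tc)
            _write("correlations_geo.csv",
                   pd.concat(geo_frames, ignore_index=True) if geo_frames
                   else pd.DataFrame())
            _write("correlations_traits.csv",
                   pd.concat(trait_frames, ignore_index=True) if trait_frames
                   else pd.DataFrame())
            manifest["stages_completed"] += ["variation_stats", "correlations"]

        if config.run_climate_growth:
            stage = "climate_growth"
            mw_frames = []
            for site, chron in chronologies.items():
                clim = climates[site]
                start = config.cg_start or max(int(chron.years[0]),
                                               int(clim.years[0]))
                end = config.cg_end or min(int(chron.years[-1]),
                                           int(clim.years[-1]))
                results = climate_growth_windows(
                    chron, clim, start, end, config.cg_window_length,
                    config.cg_months, config.n_boot, seed=config.seed)
                t = windows_table(results)
                t.insert(0, "site", site)
                mw_frames.append(t)
            _write("moving_windows.csv", pd.concat(mw_frames, ignore_index=True))
            manifest["stages_completed"].append(stage)

        manifest["complete"] = True
        _manifest()
        return manifest
    except PipelineError:
        _manifest()
        raise
    except Exception as exc:
        _manifest()
        raise PipelineError(f"{stage}: {exc}") from exc
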