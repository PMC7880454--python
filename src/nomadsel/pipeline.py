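"""End-to-end pipeline: simulate -> prepare -> rsf -> ssf -> report.

Each stage reads only the artifacts of earlier stages from the output
directory, writes CSV/TIFF/JSON artifacts plus a manifest (stage, config
hash, seed, inputs), and never mutates upstream artifacts.  All
randomness derives from the master seed through named seed sequences, so
reruns with the same configuration are byte-identical for the
deterministic stages.

The simulated demo landscape has a greenness series covering each
growing season and a year-round categorical snow series; movers select
greenness in the growing season and snow-cover fraction in winter with
the configured quadratic strength.  Winter SSF entities are
individual-years, growing-season entities are individuals (with
individual-year fits additionally at the 1-day lag), mirroring how data
volume constrains the two seasons.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import availability, landscape, rsf, rss, scenes, simulate, ssf, tracks
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "rsf", "ssf", "report")
SNOW_AGG_BLOCK = 4  # 500 m cells -> 2 km mean snow fraction


def _rng(cfg: PipelineConfig, *key: str) -> np.random.Generator:
    import hashlib

    digest = hashlib.sha256("/".join(key).encode()).digest()
    h = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([cfg.seed, h])


def _manifest(cfg: PipelineConfig, stage: str, inputs: list[str],
              outputs: list[str]) -> None:
    out = Path(cfg.outdir)
    (out / f"manifest_{stage}.json").write_text(json.dumps({
        "stage": stage, "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "inputs": sorted(inputs), "outputs": sorted(outputs),
    }, indent=1))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing upstream artifact: {path}")
    return path


# ---------------------------------------------------------------------------
# simulate


def _year_scenes(cfg: PipelineConfig, year: int) -> tuple[list, list]:
    s = cfg.simulate
    green_cfg = landscape.LandscapeConfig(
        grid_nx=s.grid_nx, grid_ny=s.grid_ny, cell_size=s.cell_size,
        correlation_length=s.correlation_length, scene_period_days=16,
        n_scenes=7, value_mean=0.3, value_sd=0.15, value_min=-0.2, value_max=1.0,
        temporal_persistence=s.temporal_persistence,
        start_date=dt.date(year, *cfg.growing_start), kind=scenes.GREENNESS,
        rng_seed=int(_rng(cfg, "green", str(year)).integers(2**31)))
    green = landscape.generate_scene_series(green_cfg)
    snow_cfg = landscape.LandscapeConfig(
        grid_nx=s.grid_nx, grid_ny=s.grid_ny, cell_size=2 * s.cell_size,
        correlation_length=2 * s.correlation_length, scene_period_days=8,
        n_scenes=46, value_mean=0.5, value_sd=0.3, value_min=0.0, value_max=1.0,
        temporal_persistence=s.temporal_persistence,
        start_date=dt.date(year, 1, 1), kind=scenes.SNOW_FRACTION,
        rng_seed=int(_rng(cfg, "snow", str(year)).integers(2**31)))
    snow_frac = landscape.generate_scene_series(snow_cfg)
    # seasonal forcing: scenes overlapping the snow-free block carry no snow
    free_lo = dt.date(year, *cfg.growing_start)
    free_hi = dt.date(year, *cfg.growing_end)
    snow_class = []
    rng = _rng(cfg, "cloud", str(year))
    for sc in snow_frac:
        snow_free = sc.start_date >= free_lo and sc.end_date <= free_hi + dt.timedelta(days=1)
        frac = np.zeros_like(sc.values) if snow_free else sc.values
        grid = np.where(frac > 0.35, 200, 25).astype(np.int16)
        flat = rng.choice(grid.size, size=max(1, grid.size // 50), replace=False)
        grid.ravel()[flat] = 50  # clouds
        snow_class.append(replace(sc, values=grid, kind=scenes.SNOW_CLASS,
                                  scene_id=f"snow_class_{sc.start_date.isoformat()}"))
    return green, snow_class


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    s = cfg.simulate
    all_green, all_snow = [], []
    years = [2015 + k for k in range(s.n_years)]
    for year in years:
        g, sn = _year_scenes(cfg, year)
        all_green += g
        all_snow += sn
    scene_dir = out / "scenes"
    index = scenes.write_scene_series(all_green + all_snow, scene_dir)

    sim_tracks = []
    for i in range(s.n_individuals):
        ind = f"ind{i:02d}"
        segments = []
        for year in years:
            green = [sc for sc in all_green if sc.start_date.year == year]
            snow_frac = [scenes.aggregate_snow(scenes.reclassify_snow(sc), SNOW_AGG_BLOCK)
                         for sc in all_snow if sc.start_date.year == year]
            for season_scenes, tag in [(green, "g"), (snow_frac, "w")]:
                span = (min(x.start_date for x in season_scenes),
                        max(x.end_date for x in season_scenes))
                mover = simulate.MoverConfig(
                    beta1=s.beta1, beta2=s.beta2, n_candidates=s.n_candidates,
                    step_scale=s.step_scale, turn_concentration=s.turn_concentration,
                    n_days=(span[1] - span[0]).days, individual_id=ind,
                    rng_seed=int(_rng(cfg, "mover", ind, str(year), tag).integers(2**31)))
                segments.append(simulate.simulate_mover(mover, season_scenes).fixes)
        track = tracks.Track(ind, pd.concat(segments, ignore_index=True))
        track = simulate.degrade_track(track, s.drop_fraction,
                                       rng=_rng(cfg, "degrade", ind))
        sim_tracks.append(track)
    tracks_path = out / "tracks.csv"
    tracks.write_tracks_csv(sim_tracks, tracks_path)
    _manifest(cfg, "simulate", [], [str(index), str(tracks_path)])
    return {"scene_index": index, "tracks": tracks_path}


# ---------------------------------------------------------------------------
# prepare


def stage_prepare(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    scene_index = Path(cfg.scene_index) if cfg.scene_index else \
        _require(out / "scenes" / "scene_index.json", "prepare")
    tracks_path = Path(cfg.tracks_path) if cfg.tracks_path else \
        _require(out / "tracks.csv", "prepare")
    raw = scenes.read_scene_series(scene_index)
    green = [sc for sc in raw if sc.kind == scenes.GREENNESS]
    snow_class = [sc for sc in raw if sc.kind == scenes.SNOW_CLASS]
    snow_frac = [sc for sc in raw if sc.kind == scenes.SNOW_FRACTION]
    if snow_class:
        # snow classes arrive as float TIFFs; restore integer codes
        snow_class = [replace(sc, values=np.rint(sc.values).astype(np.int16))
                      for sc in snow_class]
        snow_frac = [scenes.aggregate_snow(scenes.reclassify_snow(sc), SNOW_AGG_BLOCK)
                     for sc in snow_class]
    try:
        calendar = scenes.define_growing_season(snow_frac)
    except ValueError:
        logger.info("cannot derive seasons from snow scenes; using configured calendar")
        calendar = scenes.SeasonCalendar(cfg.growing_start, cfg.growing_end)
    import yaml

    cal_path = out / "calendar.yaml"
    cal_path.write_text(yaml.safe_dump(calendar.to_dict()))
    processed = scenes.write_scene_series(green + snow_frac, out / "prepared_scenes")
    daily = [tracks.daily_average(tr) for tr in tracks.read_tracks_csv(tracks_path)]
    daily_path = out / "daily_tracks.csv"
    tracks.write_tracks_csv(daily, daily_path)
    _manifest(cfg, "prepare", [str(scene_index), str(tracks_path)],
              [str(processed), str(cal_path), str(daily_path)])
    return {"scene_index": processed, "calendar": cal_path, "daily_tracks": daily_path}


def _load_prepared(cfg: PipelineConfig, stage: str):
    out = Path(cfg.outdir)
    import yaml

    prepared = scenes.read_scene_series(
        _require(out / "prepared_scenes" / "scene_index.json", stage))
    calendar = scenes.SeasonCalendar.from_dict(
        yaml.safe_load(_require(out / "calendar.yaml", stage).read_text()))
    daily = tracks.read_tracks_csv(_require(out / "daily_tracks.csv", stage))
    season_scenes = {
        "growing": [sc for sc in prepared if sc.kind == scenes.GREENNESS],
        "winter": [sc for sc in prepared if sc.kind == scenes.SNOW_FRACTION],
    }
    return season_scenes, calendar, daily


# ---------------------------------------------------------------------------
# rsf


def stage_rsf(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    season_scenes, calendar, daily = _load_prepared(cfg, "rsf")
    artifacts = {}
    for season in ("growing", "winter"):
        scs = season_scenes[season]
        if not scs:
            continue

        def builder(m: int, _scs=scs, _season=season) -> pd.DataFrame:
            return availability.build_use_availability_table(
                daily, _scs, calendar, _season, m,
                _rng(cfg, "rsf", _season, f"m{m}"),
                weight_available=cfg.rsf.weight_available, grid_n=cfg.rsf.grid_n)

        table = builder(cfg.rsf.report_multiplier)
        if table.empty:
            logger.warning("rsf %s: empty table, skipped", season)
            continue
        table_path = out / f"rsf_table_{season}.csv"
        table.to_csv(table_path, index=False)
        fits = {}
        for shape in ("linear", "quadratic"):
            spec = rsf.ModelSpec(shape=shape,
                                 weight_available=cfg.rsf.weight_available)
            fits[shape] = rsf.simplification_ladder(table, spec,
                                                    model_id=f"{season}_{shape}")
        comp = rsf.compare_shapes(fits["linear"], fits["quadratic"])
        comp.to_csv(out / f"rsf_comparison_{season}.csv", index=False)
        (out / f"rsf_fits_{season}.json").write_text(json.dumps(
            {k: f.to_dict() for k, f in fits.items()}, indent=1))
        top_shape = comp.iloc[0]["hypothesis"]
        surviving = tuple(t for t in rsf.RANDOM_TERMS
                          if t in fits[top_shape].variance_components)
        stability = rsf.multiplier_stability(
            builder, cfg.rsf.multipliers,
            rsf.ModelSpec(shape=top_shape, random_terms=surviving,
                          weight_available=cfg.rsf.weight_available))
        stability.to_csv(out / f"rsf_stability_{season}.csv", index=False)
        artifacts[season] = table_path
    _manifest(cfg, "rsf", [str(out / "daily_tracks.csv")],
              [str(p) for p in out.glob("rsf_*")])
    return artifacts


# ---------------------------------------------------------------------------
# ssf


def _season_steps(track: tracks.Track, calendar: scenes.SeasonCalendar,
                  season: str, lag: int, year: int | None = None) -> pd.DataFrame:
    df = track.fixes
    dates = df["timestamp"].dt.date
    keep = np.array([calendar.season_of(d) == season for d in dates])
    if year is not None:
        keep &= np.array([calendar.season_year(d) == year for d in dates])
    sub = tracks.Track(track.individual_id, df.loc[keep]) if keep.any() else None
    if sub is None or len(sub) < 3:
        return pd.DataFrame()
    return tracks.steps_for_track(sub, lag)


def stage_ssf(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    season_scenes, calendar, daily = _load_prepared(cfg, "ssf")
    class_rows = []
    for season in ("growing", "winter"):
        scs = season_scenes[season]
        if not scs:
            continue
        years = sorted({calendar.season_year(sc.start_date) for sc in scs})
        for lag in cfg.ssf.lags:
            pooled = [s for tr in daily
                      for s in [_season_steps(tr, calendar, season, lag)] if not s.empty]
            if not pooled:
                continue
            try:
                kernel = ssf.build_kernel(pd.concat(pooled, ignore_index=True), lag)
            except ValueError as e:
                logger.info("ssf %s lag %d: %s", season, lag, e)
                continue
            entities = []
            if season == "growing":
                entities += [(tr, None) for tr in daily]
                if lag == 1:
                    entities += [(tr, y) for tr in daily for y in years]
            else:
                entities += [(tr, y) for tr in daily for y in years]
            for tr, year in entities:
                steps = _season_steps(tr, calendar, season, lag, year)
                if steps.empty:
                    continue
                strata = ssf.generate_pseudo_steps(
                    steps, kernel, cfg.ssf.report_k, scs,
                    _rng(cfg, "ssf", season, str(lag), tr.individual_id, str(year)),
                    individual_id=tr.individual_id, season=season, year=year)
                if strata.n_strata < cfg.ssf.min_steps:
                    logger.info("ssf %s lag %d %s year=%s: %d strata < %d, skipped",
                                season, lag, tr.individual_id, year,
                                strata.n_strata, cfg.ssf.min_steps)
                    continue
                fit_l = ssf.fit_clogit(strata, "linear", cfg.ssf.min_steps)
                fit_q = ssf.fit_clogit(strata, "quadratic", cfg.ssf.min_steps)
                cls = ssf.classify_selection(fit_l, fit_q, cfg.ssf.alpha)
                class_rows.append({
                    "season": season, "lag_days": lag,
                    "individual_id": tr.individual_id,
                    "year": -1 if year is None else year,
                    "n_strata": strata.n_strata, "category": cls.category,
                    "top_shape": cls.top_shape, "significant": cls.significant,
                    "peak_covariate": cls.peak_covariate,
                    "beta1": (fit_q if cls.top_shape == "quadratic" else fit_l).beta["z"],
                    "beta2": fit_q.beta["z2"] if cls.top_shape == "quadratic" else np.nan,
                    "z_low": float(np.quantile(strata.z, cfg.rss.trim)),
                    "z_high": float(np.quantile(strata.z, 1 - cfg.rss.trim)),
                })
    cls_df = pd.DataFrame(class_rows)
    cls_path = out / "ssf_classifications.csv"
    cls_df.to_csv(cls_path, index=False)
    switch_rows = []
    if not cls_df.empty:
        for (season, lag), g in cls_df[cls_df["year"] >= 0].groupby(
                ["season", "lag_days"]):
            table, fraction = ssf.switching_summary(g)
            switch_rows.append({"season": season, "lag_days": lag,
                                "n_assessable": len(table),
                                "n_switched": int(table["switched"].sum()) if len(table) else 0,
                                "switch_fraction": fraction})
    pd.DataFrame(switch_rows).to_csv(out / "ssf_switching.csv", index=False)
    _manifest(cfg, "ssf", [str(out / "daily_tracks.csv")],
              [str(cls_path), str(out / "ssf_switching.csv")])
    return {"classifications": cls_path}


# ---------------------------------------------------------------------------
# report


def stage_report(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    comparisons, top_fits, pooled = {}, {}, {}
    for season in ("growing", "winter"):
        comp_path = out / f"rsf_comparison_{season}.csv"
        if not comp_path.exists():
            continue
        comp = pd.read_csv(comp_path)
        comparisons[season] = comp
        fits = json.loads((out / f"rsf_fits_{season}.json").read_text())
        top = fits[comp.iloc[0]["hypothesis"]]
        top_fits[season] = rsf.FitResult(**top)
        pooled[season] = pd.read_csv(out / f"rsf_table_{season}.csv")["covariate"].to_numpy()
    artifacts = {}
    if comparisons:
        pop = rss.population_report(comparisons, top_fits, pooled, cfg.rss.trim)
        for name, df in pop.items():
            p = out / f"report_population_{name}.csv"
            df.to_csv(p, index=False)
            artifacts[name] = p
    cls_path = _require(out / "ssf_classifications.csv", "report")
    cls_df = pd.read_csv(cls_path)
    if not cls_df.empty:
        ind = rss.individual_report(cls_df)
        ind["category_table"].to_csv(out / "report_individual_categories.csv",
                                     index=False)
        curves = []
        for _, r in cls_df[cls_df["significant"] == True].iterrows():  # noqa: E712
            b2 = None if pd.isna(r["beta2"]) else float(r["beta2"])
            if r["z_low"] < r["z_high"]:
                mid = (r["z_low"] + r["z_high"]) / 2
                c = rss.rss_curve(float(r["beta1"]), b2, r["z_low"], r["z_high"],
                                  mid, model_id=f"{r['season']}_{r['individual_id']}"
                                  f"_y{r['year']}_lag{r['lag_days']}",
                                  n_points=cfg.rss.n_grid)
                curves.append(c.to_frame())
        pd.concat(curves, ignore_index=True).to_csv(
            out / "report_individual_curves.csv", index=False) if curves else None
    _manifest(cfg, "report", [str(cls_path)],
              [str(p) for p in out.glob("report_*")])
    return artifacts


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, stage: str = "all") -> dict:
    """Run one stage or the full chain in dependency order."""
    cfg.validate()
    if stage not in STAGES + ("all",):
        raise ValueError(f"unknown stage '{stage}'; allowed: {STAGES + ('all',)}")
    todo = STAGES if stage == "all" else (stage,)
    artifacts = {}
    for st in todo:
        fn = {"simulate": stage_simulate, "prepare": stage_prepare,
              "rsf": stage_rsf, "ssf": stage_ssf, "report": stage_report}[st]
        logger.info("running stage %s", st)
        artifacts[st] = fn(cfg)
    return artifacts
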