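"""Population-level use-availability design.

Availability for each individual-season-year is its 100% minimum convex
polygon (the convex hull of that entity's daily locations), optionally
clipped to a study boundary.  Pseudo-absences are allocated scene by
scene — each covariate scene receives ``multiplier`` times as many random
points as the individual has used points in that scene's window — and
sampled with spatial stratification: the polygon's bounding box is divided
into a regular grid, cells receive counts proportional to their in-polygon
area, and points are rejection-sampled into each cell's intersection with
the polygon.

Covariates are read from the date-matched scene at the containing cell;
rows landing on nodata are dropped (used side) or resampled a bounded
number of times then dropped (available side), with counts logged.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, box

from .scenes import RasterScene, SeasonCalendar, scene_for_date
from .tracks import Track

logger = logging.getLogger(__name__)

MULTIPLIERS = (1, 2, 5, 10, 20)


@dataclass
class AvailabilityDomain:
    """One individual-season-year's availability polygon (100% MCP)."""

    individual_id: str
    season: str
    year: int
    polygon: Polygon
    source_point_count: int


def build_mcp(points: np.ndarray, boundary: Polygon | None = None) -> Polygon:
    """100% minimum convex polygon of points, clipped to a boundary if given."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError(f"MCP needs >= 3 points, got {len(pts)}")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("points are collinear; MCP undefined")
    if boundary is not None:
        hull = hull.intersection(boundary)
        if hull.is_empty or hull.area == 0:
            raise ValueError("MCP lies entirely outside the study boundary")
    return hull


def sample_pseudo_absences(
    domain: AvailabilityDomain,
    per_scene_counts: dict[str, int],
    multiplier: int,
    rng: np.random.Generator,
    grid_n: int = 10,
) -> pd.DataFrame:
    """Grid-stratified random points in the polygon, allocated per scene.

    Returns a frame with columns scene_id, x, y; each scene gets exactly
    ``multiplier * n_used`` points.  Starved stratification cells fall back
    to uniform rejection sampling over the whole polygon (logged).
    """
    if multiplier not in MULTIPLIERS:
        raise ValueError(f"multiplier must be one of {MULTIPLIERS}")
    poly = domain.polygon
    if poly.area <= 0:
        raise ValueError("degenerate availability polygon")
    minx, miny, maxx, maxy = poly.bounds
    xs = np.linspace(minx, maxx, grid_n + 1)
    ys = np.linspace(miny, maxy, grid_n + 1)
    cells, areas = [], []
    for i in range(grid_n):
        for j in range(grid_n):
            c = box(xs[i], ys[j], xs[i + 1], ys[j + 1])
            a = c.intersection(poly).area
            if a > 0:
                cells.append(c)
                areas.append(a)
    weights = np.asarray(areas) / np.sum(areas)

    def _stratified(n: int) -> np.ndarray:
        # proportional allocation with largest remainders
        raw = n * weights
        alloc = np.floor(raw).astype(int)
        short = n - alloc.sum()
        if short > 0:
            alloc[np.argsort(raw - np.floor(raw))[::-1][:short]] += 1
        out = np.empty((n, 2))
        k = 0
        for cell, m in zip(cells, alloc):
            if m == 0:
                continue
            cminx, cminy, cmaxx, cmaxy = cell.bounds
            got = 0
            for _ in range(200):  # rejection into cell ∩ polygon
                need = m - got
                if need == 0:
                    break
                px = rng.uniform(cminx, cmaxx, size=4 * need)
                py = rng.uniform(cminy, cmaxy, size=4 * need)
                ok = shapely.contains_xy(poly, px, py)
                take = min(need, int(ok.sum()))
                out[k + got:k + got + take] = np.column_stack([px[ok], py[ok]])[:take]
                got += take
            if got < m:  # cell starvation: uniform over the polygon
                logger.info("stratification cell starved; falling back to uniform")
                while got < m:
                    px = rng.uniform(minx, maxx, size=8 * (m - got))
                    py = rng.uniform(miny, maxy, size=8 * (m - got))
                    ok = shapely.contains_xy(poly, px, py)
                    take = min(m - got, int(ok.sum()))
                    out[k + got:k + got + take] = np.column_stack([px[ok], py[ok]])[:take]
                    got += take
            k += m
        return out

    frames = []
    for scene_id, n_used in sorted(per_scene_counts.items()):
        n = multiplier * int(n_used)
        if n == 0:
            continue
        pts = _stratified(n)
        frames.append(pd.DataFrame({"scene_id": scene_id, "x": pts[:, 0], "y": pts[:, 1]}))
    if not frames:
        return pd.DataFrame(columns=["scene_id", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def extract_covariate(points: pd.DataFrame, scenes: Sequence[RasterScene]) -> pd.DataFrame:
    """Attach the covariate from each point's date- or id-matched scene.

    Points on nodata or outside the raster extent are dropped (logged).
    Input needs columns x, y and either date or scene_id.
    """
    by_id = {sc.scene_id: sc for sc in scenes}
    df = points.reset_index(drop=True).copy()
    if "scene_id" not in df.columns:
        if "date" not in df.columns:
            raise ValueError("points need a 'date' or 'scene_id' column")
        dates = pd.to_datetime(df["date"])
        df["scene_id"] = [scene_for_date(scenes, d.date()).scene_id for d in dates]
    z = np.full(len(df), np.nan)
    for sid, g in df.groupby("scene_id"):
        sc = by_id[sid]
        z[g.index.to_numpy()] = sc.value_at(g["x"].to_numpy(), g["y"].to_numpy())
    df["covariate"] = z
    n_drop = int(np.isnan(z).sum())
    if n_drop:
        logger.info("extract_covariate: dropped %d point(s) on nodata/outside extent", n_drop)
    return df.loc[~np.isnan(z)].reset_index(drop=True)


def build_use_availability_table(
    daily_tracks: Sequence[Track],
    scenes: Sequence[RasterScene],
    calendar: SeasonCalendar,
    season: str,
    multiplier: int,
    rng: np.random.Generator,
    boundary: Polygon | None = None,
    weight_available: float = 1000.0,
    grid_n: int = 10,
    max_resample: int = 10,
) -> pd.DataFrame:
    """Assemble the RSF design table for one season.

    Rows carry individual_id, year, scene_id, used (1/0), weight (1 for
    used, ``weight_available`` otherwise), covariate, x, y, date.  Per
    individual and scene the available:used ratio equals ``multiplier``
    before nodata drops; available points landing on nodata are resampled
    up to ``max_resample`` times to preserve the ratio, then dropped.
    """
    span = (min(s.start_date for s in scenes), max(s.end_date for s in scenes))
    rows = []
    for track in daily_tracks:
        df = track.fixes.copy()
        df["date"] = df["timestamp"].dt.date
        df = df[(df["date"] >= span[0]) & (df["date"] < span[1])]
        df = df[[calendar.season_of(d) == season for d in df["date"]]]
        if df.empty:
            continue
        df["year"] = [calendar.season_year(d) for d in df["date"]]
        if boundary is not None:
            inside = shapely.contains_xy(boundary, df["x"].to_numpy(), df["y"].to_numpy())
            df = df.loc[inside]
        for year, g in df.groupby("year"):
            if len(g) < 3:
                logger.info("%s %s %s: fewer than 3 points, no MCP", track.individual_id, season, year)
                continue
            try:
                poly = build_mcp(g[["x", "y"]].to_numpy(), boundary)
            except ValueError as e:
                logger.info("%s %s %s: %s", track.individual_id, season, year, e)
                continue
            domain = AvailabilityDomain(track.individual_id, season, int(year), poly, len(g))
            used = extract_covariate(g[["x", "y", "date"]].reset_index(drop=True), scenes)
            if used.empty:
                continue
            counts = used["scene_id"].value_counts().to_dict()
            used["used"], used["weight"] = 1, 1.0
            used["individual_id"], used["year"] = track.individual_id, int(year)
            rows.append(used)
            avail = sample_pseudo_absences(domain, counts, multiplier, rng, grid_n)
            got = extract_covariate(avail, scenes)
            for _ in range(max_resample):  # top up nodata losses per scene
                have = got["scene_id"].value_counts().to_dict()
                short = {sid: multiplier * n - have.get(sid, 0) for sid, n in counts.items()
                         if multiplier * n > have.get(sid, 0)}
                if not short:
                    break
                extra = sample_pseudo_absences(
                    domain, {k: v for k, v in short.items()}, 1, rng, grid_n)
                got = pd.concat([got, extract_covariate(extra, scenes)], ignore_index=True)
            got["used"], got["weight"] = 0, float(weight_available)
            got["individual_id"], got["year"] = track.individual_id, int(year)
            sid_dates = {sc.scene_id: sc.start_date for sc in scenes}
            got["date"] = got["scene_id"].map(sid_dates)
            rows.append(got)
    if not rows:
        return pd.DataFrame(columns=["individual_id", "year", "scene_id", "used",
                                     "weight", "covariate", "x", "y", "date"])
    table = pd.concat(rows, ignore_index=True)
    return table[["individual_id", "year", "scene_id", "used", "weight",
                  "covariate", "x", "y", "date"]]
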