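"""Dated raster covariate scenes and season handling.

A :class:`RasterScene` is one time-indexed grid of a single environmental
covariate: vegetation greenness (NDVI-like, roughly in [-0.2, 1], 16-day
composites), a categorical snow product (8-day composites), or the
snow-cover fraction derived from it.  Scenes tile time with half-open
windows ``[start, start + period_days)`` so that every date inside a
series' span maps to exactly one scene.

The winter covariate is built in two steps mirroring the standard MODIS
snow-product workflow: the categorical grid is reclassified to binary
snow / no-snow (everything else becomes nodata), then block-aggregated to
a coarser mean snow-cover fraction so a location's value reflects its
surroundings rather than a single pixel.

Seasons are defined from snow presence: the growing season is the longest
block of calendar dates that were snow-free in every observed year; the
remainder of the year is winter.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Categorical snow-product codes (MOD10A2-style 8-day maximum snow extent).
SNOW_CLASS_CODES = {
    0: "missing",
    1: "no decision",
    11: "night",
    25: "no snow",
    37: "lake",
    39: "ocean",
    50: "cloud",
    100: "lake ice",
    200: "snow",
    254: "detector saturated",
    255: "fill",
}

GREENNESS = "greenness"
SNOW_CLASS = "snow_class"
SNOW_FRACTION = "snow_fraction"

_REF_YEAR = 2015  # non-leap reference year for month-day arithmetic


@dataclass
class RasterScene:
    """One dated single-covariate grid.

    ``values`` is indexed ``[iy, ix]`` with the origin ``(x0, y0)`` at the
    lower-left corner and y increasing with the row index.  Continuous
    scenes use NaN as nodata; categorical scenes hold integer codes from
    :data:`SNOW_CLASS_CODES`.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float
    start_date: dt.date
    period_days: int
    kind: str = GREENNESS
    scene_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("scene values must be a 2-D array")
        if self.period_days not in (8, 16):
            raise ValueError(f"period_days must be 8 or 16, got {self.period_days}")
        if not self.scene_id:
            self.scene_id = f"{self.kind}_{self.start_date.isoformat()}"

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def end_date(self) -> dt.date:
        """First date *not* covered (half-open window)."""
        return self.start_date + dt.timedelta(days=self.period_days)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def covers(self, date: dt.date) -> bool:
        return self.start_date <= date < self.end_date

    def cell_index(self, x, y):
        """Row/column indices of the cells containing planar points."""
        ix = np.floor((np.asarray(x, float) - self.x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, float) - self.y0) / self.cell_size).astype(int)
        return iy, ix

    def value_at(self, x, y):
        """Covariate at point locations; NaN outside the grid extent."""
        iy, ix = self.cell_index(x, y)
        iy = np.atleast_1d(iy)
        ix = np.atleast_1d(ix)
        out = np.full(iy.shape, np.nan)
        ok = (iy >= 0) & (iy < self.ny) & (ix >= 0) & (ix < self.nx)
        vals = self.values.astype(float)
        out[ok] = vals[iy[ok], ix[ok]]
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out[0])
        return out


def reclassify_snow(scene: RasterScene) -> RasterScene:
    """Collapse a categorical snow grid to {1 = snow, 0 = no snow, NaN}.

    Every non-snow, non-no-snow class (cloud, night, lake, ...) carries no
    information about snow cover and becomes nodata.  Unknown codes are an
    error rather than silently nodata.
    """
    if scene.kind != SNOW_CLASS:
        raise ValueError(f"expected a {SNOW_CLASS} scene, got {scene.kind}")
    codes = np.asarray(scene.values)
    unknown = set(np.unique(codes).tolist()) - set(SNOW_CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown snow class code(s): {sorted(unknown)}")
    out = np.full(codes.shape, np.nan)
    out[codes == 200] = 1.0
    out[codes == 25] = 0.0
    return replace(scene, values=out, kind=SNOW_FRACTION,
                   scene_id=scene.scene_id + "_binary")


def aggregate_snow(scene: RasterScene, block_cells: int) -> RasterScene:
    """Mean snow fraction over ``block_cells`` x ``block_cells`` blocks.

    Nodata cells are excluded from each block mean; a fully-nodata block is
    nodata.  Trailing rows/columns that do not fill a block are dropped.
    """
    if scene.kind != SNOW_FRACTION:
        raise ValueError(f"expected a {SNOW_FRACTION} scene, got {scene.kind}")
    if block_cells < 1:
        raise ValueError("block_cells must be >= 1")
    b = int(block_cells)
    ny, nx = (scene.ny // b) * b, (scene.nx // b) * b
    v = scene.values[:ny, :nx].reshape(ny // b, b, nx // b, b)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nodata blocks
        out = np.nanmean(v, axis=(1, 3))
    return replace(scene, values=out, cell_size=scene.cell_size * b,
                   scene_id=scene.scene_id + f"_agg{b}")


def scene_for_date(scenes: Sequence[RasterScene], date: dt.date) -> RasterScene:
    """The unique scene whose half-open window contains ``date``."""
    for sc in scenes:
        if sc.covers(date):
            return sc
    raise ValueError(f"date {date} not covered by the scene series")


def check_tiling(scenes: Sequence[RasterScene]) -> None:
    """Raise if consecutive scenes overlap or leave gaps."""
    ordered = sorted(scenes, key=lambda s: s.start_date)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_date != b.start_date:
            raise ValueError(
                f"scenes do not tile time: {a.scene_id} ends {a.end_date}, "
                f"{b.scene_id} starts {b.start_date}"
            )


# ---------------------------------------------------------------------------
# Seasons


@dataclass
class SeasonCalendar:
    """Two-season partition of the year by (month, day) boundaries.

    ``growing_start``..``growing_end`` inclusive is the growing season;
    every other date is winter.  A winter season-year is labelled by the
    calendar year in which that winter starts.
    """

    growing_start: tuple[int, int] = (5, 9)
    growing_end: tuple[int, int] = (8, 29)

    def _doy(self, month: int, day: int) -> int:
        if (month, day) == (2, 29):
            month, day = 2, 28
        return dt.date(_REF_YEAR, month, day).timetuple().tm_yday

    def season_of(self, date: dt.date) -> str:
        d = self._doy(date.month, date.day)
        lo = self._doy(*self.growing_start)
        hi = self._doy(*self.growing_end)
        if lo <= hi:
            return "growing" if lo <= d <= hi else "winter"
        return "growing" if (d >= lo or d <= hi) else "winter"

    def season_year(self, date: dt.date) -> int:
        """Season-year label; a winter spanning New Year is one season."""
        if self.season_of(date) == "growing":
            return date.year
        # winter anchored at its starting calendar year
        start_doy = self._doy(*self.growing_end)
        return date.year if self._doy(date.month, date.day) > start_doy else date.year - 1

    def to_dict(self) -> dict:
        return {"growing_start": list(self.growing_start),
                "growing_end": list(self.growing_end)}

    @classmethod
    def from_dict(cls, d: dict) -> "SeasonCalendar":
        return cls(tuple(d["growing_start"]), tuple(d["growing_end"]))


def define_growing_season(
    snow_scenes: Iterable[RasterScene],
    snow_threshold: float = 0.0,
    mask: np.ndarray | None = None,
) -> SeasonCalendar:
    """Derive the growing season as the longest run of always-snow-free dates.

    A calendar date (month-day) is snow-free when no covering scene in any
    observed year records snow anywhere (fraction > ``snow_threshold``,
    optionally restricted to a boolean ``mask`` of study-area cells).
    Dates never covered by a scene are treated as not snow-free.
    """
    snowy = np.zeros(366, dtype=bool)
    covered = np.zeros(366, dtype=bool)
    for sc in snow_scenes:
        if sc.kind != SNOW_FRACTION:
            raise ValueError("define_growing_season expects snow_fraction scenes")
        v = sc.values if mask is None else np.where(mask, sc.values, np.nan)
        with np.errstate(invalid="ignore"):
            has_snow = bool(np.any(v > snow_threshold))
        for k in range(sc.period_days):
            date = sc.start_date + dt.timedelta(days=k)
            d = date.replace(day=28) if (date.month, date.day) == (2, 29) else date
            doy = dt.date(_REF_YEAR, d.month, d.day).timetuple().tm_yday - 1
            covered[doy] = True
            if has_snow:
                snowy[doy] = True
    free = covered & ~snowy
    if not free.any():
        raise ValueError("no snow-free calendar date in any year; cannot define a growing season")
    # longest circular run of snow-free day-of-year
    idx = np.arange(365)
    free365 = free[:365]
    best_start, best_len = 0, 0
    run_start, run_len = None, 0
    for d in np.concatenate([idx, idx]):  # wrap once around the year
        if free365[d]:
            if run_start is None:
                run_start, run_len = int(d), 0
            run_len += 1
            if run_len > best_len and run_len <= 365:
                best_start, best_len = run_start, run_len
        else:
            run_start, run_len = None, 0
    start = dt.date(_REF_YEAR, 1, 1) + dt.timedelta(days=best_start)
    end = dt.date(_REF_YEAR, 1, 1) + dt.timedelta(days=(best_start + best_len - 1) % 365)
    cal = SeasonCalendar((start.month, start.day), (end.month, end.day))
    logger.info("growing season defined as %s to %s", cal.growing_start, cal.growing_end)
    return cal


# ---------------------------------------------------------------------------
# I/O: TIFF grids + JSON sidecar index


def write_scene_series(scenes: Sequence[RasterScene], directory: str | Path) -> Path:
    """Write scenes as single-band TIFFs plus a JSON index; returns index path."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sc in scenes:
        fname = f"{sc.scene_id}.tif"
        # TIFF rows run top-to-bottom; our grids run bottom-to-top
        tifffile.imwrite(directory / fname, sc.values[::-1].astype(np.float32))
        entries.append({
            "path": fname,
            "x0": sc.x0, "y0": sc.y0, "cell_size": sc.cell_size,
            "start_date": sc.start_date.isoformat(),
            "period_days": sc.period_days,
            "kind": sc.kind, "scene_id": sc.scene_id,
        })
    index = directory / "scene_index.json"
    index.write_text(json.dumps(entries, indent=1))
    return index


def read_scene_series(index_path: str | Path) -> list[RasterScene]:
    import tifffile

    index_path = Path(index_path)
    entries = json.loads(index_path.read_text())
    scenes = []
    for e in entries:
        values = np.asarray(tifffile.imread(index_path.parent / e["path"]))[::-1]
        scenes.append(RasterScene(
            values=values, x0=e["x0"], y0=e["y0"], cell_size=e["cell_size"],
            start_date=dt.date.fromisoformat(e["start_date"]),
            period_days=e["period_days"], kind=e["kind"], scene_id=e["scene_id"],
        ))
    return scenes
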