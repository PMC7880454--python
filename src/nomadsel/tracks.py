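"""Relocation tracks: ingestion, daily regularization, and multi-lag steps.

A :class:`Track` is one individual's time-ordered planar fixes.  Sub-daily
fixes (hourly collars) are collapsed to a daily average location; analysis
then runs on daily fixes.  Steps at a lag of 1, 5 or 10 days are extracted
from maximal runs of fixes spaced exactly that many calendar days apart —
multi-day lags use every phase offset, so a lag-5 series starting on day 0
and one starting on day 1 form separate runs.  A run needs at least three
points: that is the minimum to define a relative turn angle.

Turn angles are signed (counter-clockwise positive) differences between
successive step headings, wrapped to (-pi, pi].  A zero-length step has no
heading, so the following step's turn angle is undefined (NaN) and the
step is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAGS = (1, 5, 10)


@dataclass
class Track:
    """One individual's relocation series (timestamp, x, y)."""

    individual_id: str
    fixes: pd.DataFrame  # columns timestamp (datetime64), x, y
    fix_interval: float = 1.0  # nominal days between fixes

    def __post_init__(self) -> None:
        df = self.fixes.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.sort_values("timestamp").reset_index(drop=True)
        if df["timestamp"].duplicated().any():
            df = df.drop_duplicates("timestamp").reset_index(drop=True)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError(f"track {self.individual_id}: non-finite coordinates")
        self.fixes = df

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class Step:
    """One movement step at a given lag; rows of the step frames.

    ``turn_angle`` is NaN for the first step of a run or when the previous
    step had zero length (no heading to turn from).
    """

    individual_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    displacement: float
    turn_angle: float
    lag_days: int


def read_tracks_csv(path: str | Path, delimiter: str | None = None) -> list[Track]:
    """Read tracks from CSV with columns individual_id, timestamp, x, y."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    required = {"individual_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    return [
        Track(str(ind), g[["timestamp", "x", "y"]].reset_index(drop=True))
        for ind, g in df.groupby("individual_id", sort=True)
    ]


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        g = tr.fixes.copy()
        g.insert(0, "individual_id", tr.individual_id)
        frames.append(g)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def daily_average(track: Track) -> Track:
    """One fix per calendar day at the centroid of that day's fixes."""
    df = track.fixes
    day = df["timestamp"].dt.normalize()
    g = df.groupby(day, sort=True)[["x", "y"]].mean().reset_index()
    g = g.rename(columns={"timestamp": "timestamp"})
    g["timestamp"] = g["timestamp"] + pd.Timedelta(hours=12)
    return Track(track.individual_id, g[["timestamp", "x", "y"]], fix_interval=1.0)


def extract_runs(track: Track, lag_days: int, min_points: int = 3) -> list[pd.DataFrame]:
    """Maximal runs of daily fixes spaced exactly ``lag_days`` apart.

    Requires at most one fix per calendar day (apply :func:`daily_average`
    first).  Runs shorter than ``min_points`` are discarded.  All phase
    offsets contribute runs for multi-day lags.
    """
    if lag_days not in LAGS:
        raise ValueError(f"lag_days must be one of {LAGS}, got {lag_days}")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    df = track.fixes
    if df.empty:
        return []
    days = (df["timestamp"].dt.normalize() - pd.Timestamp("1970-01-01")).dt.days.to_numpy()
    if len(np.unique(days)) != len(days):
        raise ValueError("multiple fixes per day; run daily_average first")
    order = np.argsort(days)
    days, df = days[order], df.iloc[order].reset_index(drop=True)
    runs: list[pd.DataFrame] = []
    for phase in range(lag_days):
        sel = np.where(days % lag_days == phase)[0]
        if sel.size == 0:
            continue
        gaps = np.diff(days[sel]) != lag_days
        for chunk in np.split(sel, np.where(gaps)[0] + 1):
            if len(chunk) >= min_points:
                run = df.iloc[chunk].reset_index(drop=True)
                run.attrs["individual_id"] = track.individual_id
                run.attrs["lag_days"] = lag_days
                runs.append(run)
    return runs


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(w, -np.pi), np.pi, w)


def steps_from_runs(runs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Steps (consecutive point pairs) with displacement, heading, turn angle.

    The first step of a run, and any step following a zero-length step, has
    an undefined (NaN) turn angle.  Zero-length steps are retained and
    flagged ``zero_length``.
    """
    rows = []
    for run_id, run in enumerate(runs):
        x = run["x"].to_numpy(float)
        y = run["y"].to_numpy(float)
        t = run["timestamp"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        disp = np.hypot(dx, dy)
        heading = np.where(disp > 0, np.arctan2(dy, dx), np.nan)
        turn = np.full(len(dx), np.nan)
        if len(dx) > 1:
            turn[1:] = _wrap_angle(heading[1:] - heading[:-1])
        rows.append(pd.DataFrame({
            "individual_id": run.attrs.get("individual_id", ""),
            "lag_days": run.attrs.get("lag_days", 1),
            "run_id": run_id,
            "start_time": t[:-1], "end_time": t[1:],
            "x0": x[:-1], "y0": y[:-1], "x1": x[1:], "y1": y[1:],
            "displacement": disp, "heading": heading,
            "turn_angle": turn, "zero_length": disp == 0,
        }))
    if not rows:
        return pd.DataFrame(columns=[
            "individual_id", "lag_days", "run_id", "start_time", "end_time",
            "x0", "y0", "x1", "y1", "displacement", "heading", "turn_angle",
            "zero_length"])
    return pd.concat(rows, ignore_index=True)


def steps_for_track(track: Track, lag_days: int, min_points: int = 3) -> pd.DataFrame:
    """Convenience: runs then steps for one daily track at one lag."""
    return steps_from_runs(extract_runs(track, lag_days, min_points))
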