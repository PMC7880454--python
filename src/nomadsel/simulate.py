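"""Selection-driven movement simulation on dynamic landscapes.

Each simulated day the mover draws ``n_candidates`` candidate endpoints
from an explicit step kernel — gamma-distributed step lengths with mean
``step_scale`` and von-Mises turn angles around the previous heading —
reads the covariate z at each candidate from the date-matched scene, and
selects one endpoint with probability proportional to

    exp(beta1 * z + beta2 * z**2).

With beta1 = beta2 = 0 this collapses to an unbiased correlated random
walk; nonzero coefficients produce exactly the discrete-choice estimand a
step-selection function targets, so fits on simulated tracks can be
checked against known truth.  Candidates falling outside the landscape
are redrawn a bounded number of times, then reflected at the boundary.

:func:`degrade_track` emulates collar imperfections: random missed fixes
and optional expansion of daily fixes into jittered hourly bursts so the
daily-averaging path is exercised.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scenes import RasterScene, scene_for_date
from .tracks import Track

logger = logging.getLogger(__name__)


@dataclass
class MoverConfig:
    beta1: float = 0.0
    beta2: float = 0.0
    n_candidates: int = 30
    step_scale: float = 2000.0       # metres, mean daily displacement
    step_shape: float = 2.0          # gamma shape of the step-length law
    turn_concentration: float = 1.0  # von Mises kappa
    n_days: int = 100
    start_xy: tuple[float, float] | None = None  # default: landscape centre
    individual_id: str = "sim-0"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_candidates < 2:
            problems.append("n_candidates must be >= 2")
        if self.step_scale <= 0:
            problems.append("step_scale must be positive")
        if self.n_days < 3:
            problems.append("n_days must be >= 3")
        if problems:
            raise ValueError("invalid MoverConfig: " + "; ".join(problems))


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (mirror at the boundaries)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def simulate_mover(cfg: MoverConfig, scenes: Sequence[RasterScene]) -> Track:
    """Simulate one mover; returns a daily-fix :class:`~nomadsel.tracks.Track`."""
    ordered = sorted(scenes, key=lambda s: s.start_date)
    start_date = ordered[0].start_date
    end_date = ordered[-1].end_date
    if (end_date - start_date).days < cfg.n_days:
        raise ValueError(
            f"scene series covers {(end_date - start_date).days} days, "
            f"need {cfg.n_days}")
    rng = np.random.default_rng(cfg.rng_seed)
    xmin, ymin, xmax, ymax = ordered[0].bounds
    pos = np.array(cfg.start_xy if cfg.start_xy is not None
                   else [(xmin + xmax) / 2, (ymin + ymax) / 2], dtype=float)
    heading = rng.uniform(-np.pi, np.pi)
    scale = cfg.step_scale / cfg.step_shape  # gamma mean = shape * scale

    times, xs, ys = [], [], []
    n_reflected = 0
    for day in range(cfg.n_days):
        date = start_date + dt.timedelta(days=day)
        times.append(pd.Timestamp(date) + pd.Timedelta(hours=12))
        xs.append(pos[0])
        ys.append(pos[1])
        if day == cfg.n_days - 1:
            break
        scene = scene_for_date(ordered, date + dt.timedelta(days=1))
        lengths = rng.gamma(cfg.step_shape, scale, size=cfg.n_candidates)
        turns = rng.vonmises(0.0, cfg.turn_concentration, size=cfg.n_candidates)
        cand_heading = heading + turns
        ex = pos[0] + lengths * np.cos(cand_heading)
        ey = pos[1] + lengths * np.sin(cand_heading)
        inside = (ex >= xmin) & (ex <= xmax) & (ey >= ymin) & (ey <= ymax)
        for _ in range(20):  # bounded redraw of out-of-grid candidates
            bad = ~inside
            if not bad.any():
                break
            nbad = int(bad.sum())
            l2 = rng.gamma(cfg.step_shape, scale, size=nbad)
            t2 = rng.vonmises(0.0, cfg.turn_concentration, size=nbad)
            cand_heading[bad] = heading + t2
            ex[bad] = pos[0] + l2 * np.cos(cand_heading[bad])
            ey[bad] = pos[1] + l2 * np.sin(cand_heading[bad])
            inside = (ex >= xmin) & (ex <= xmax) & (ey >= ymin) & (ey <= ymax)
        if not inside.all():
            n_reflected += int((~inside).sum())
            ex = _reflect(ex, xmin, xmax)
            ey = _reflect(ey, ymin, ymax)
        z = np.nan_to_num(scene.value_at(ex, ey), nan=0.0)
        eta = cfg.beta1 * z + cfg.beta2 * z**2
        p = np.exp(eta - eta.max())
        j = rng.choice(cfg.n_candidates, p=p / p.sum())
        new_pos = np.array([ex[j], ey[j]])
        d = new_pos - pos
        if np.hypot(*d) > 0:
            heading = float(np.arctan2(d[1], d[0]))
        pos = new_pos
    if n_reflected:
        logger.info("%s: %d candidate endpoints reflected at the boundary",
                    cfg.individual_id, n_reflected)
    return Track(cfg.individual_id,
                 pd.DataFrame({"timestamp": times, "x": xs, "y": ys}))


def degrade_track(
    track: Track,
    drop_fraction: float = 0.0,
    hourly_burst: bool = False,
    jitter: float = 50.0,
    rng: np.random.Generator | None = None,
) -> Track:
    """Emulate collar imperfections on a daily track.

    ``drop_fraction`` of fixes are removed at random; with ``hourly_burst``
    each surviving day expands to 24 hourly fixes jittered N(0, jitter^2)
    around the daily position (round-tripping through daily averaging
    recovers the original positions up to the jitter scale).
    """
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    df = track.fixes
    keep = rng.random(len(df)) >= drop_fraction
    df = df.loc[keep].reset_index(drop=True)
    if not hourly_burst:
        return Track(track.individual_id, df, fix_interval=track.fix_interval)
    rows = []
    for _, r in df.iterrows():
        base = r["timestamp"].normalize()
        for h in range(24):
            rows.append({
                "timestamp": base + pd.Timedelta(hours=h),
                "x": r["x"] + rng.normal(0.0, jitter),
                "y": r["y"] + rng.normal(0.0, jitter),
            })
    return Track(track.individual_id, pd.DataFrame(rows), fix_interval=1 / 24)
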