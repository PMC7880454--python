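"""Synthetic dynamic landscapes: spatially autocorrelated scene series.

Fields are Gaussian random fields built by smoothing white noise with a
Gaussian kernel whose bandwidth is the configured correlation length.
Successive scenes evolve as an AR(1) process on the standardized field,

    f_t = rho * f_{t-1} + sqrt(1 - rho^2) * innovation_t,

so ``temporal_persistence`` (rho) in [0, 1] controls how much of one
composite's pattern carries into the next; rho = 1 freezes the landscape.
Values are rescaled to ``value_mean``/``value_sd`` and clamped to
``[value_min, value_max]``, which lets the same machinery emulate both a
greenness covariate (roughly [-0.2, 1], 16-day cadence) and a snow-cover
fraction ([0, 1], 8-day cadence).  A categorical mode thresholds the field
into snow / no-snow codes with a sprinkling of cloud cells, feeding the
reclassification step downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .scenes import GREENNESS, SNOW_CLASS, SNOW_FRACTION, RasterScene


@dataclass
class LandscapeConfig:
    grid_nx: int = 64
    grid_ny: int = 64
    cell_size: float = 250.0           # metres
    correlation_length: float = 2000.0  # metres; Gaussian kernel bandwidth
    scene_period_days: int = 16         # 16 greenness-like, 8 snow-like
    n_scenes: int = 7
    value_mean: float = 0.3
    value_sd: float = 0.15
    value_min: float = -0.2
    value_max: float = 1.0
    temporal_persistence: float = 0.6
    start_date: dt.date = field(default_factory=lambda: dt.date(2015, 5, 9))
    kind: str = GREENNESS
    cloud_fraction: float = 0.02        # categorical mode only
    rng_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.grid_nx < 8 or self.grid_ny < 8:
            problems.append("grid dimensions must be >= 8")
        if not (0.0 <= self.temporal_persistence <= 1.0):
            problems.append("temporal_persistence must be in [0, 1]")
        if self.value_min > self.value_max:
            problems.append("value_min must not exceed value_max")
        if self.correlation_length <= 0:
            problems.append("correlation_length must be positive")
        if self.scene_period_days not in (8, 16):
            problems.append("scene_period_days must be 8 or 16")
        if self.n_scenes < 1:
            problems.append("n_scenes must be >= 1")
        if problems:
            raise ValueError("invalid LandscapeConfig: " + "; ".join(problems))


def _standardized_field(rng: np.random.Generator, cfg: LandscapeConfig) -> np.ndarray:
    """Unit-variance smoothed-noise field with the configured range."""
    sigma = cfg.correlation_length / cfg.cell_size
    f = gaussian_filter(rng.standard_normal((cfg.grid_ny, cfg.grid_nx)), sigma,
                        mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_scene_series(cfg: LandscapeConfig) -> list[RasterScene]:
    """Generate ``cfg.n_scenes`` consecutive scenes tiling time without gaps."""
    rng = np.random.default_rng(cfg.rng_seed)
    rho = cfg.temporal_persistence
    f = _standardized_field(rng, cfg)
    scenes: list[RasterScene] = []
    for t in range(cfg.n_scenes):
        if t > 0:
            f = rho * f + np.sqrt(1.0 - rho**2) * _standardized_field(rng, cfg)
        values = np.clip(cfg.value_mean + cfg.value_sd * f,
                         cfg.value_min, cfg.value_max)
        start = cfg.start_date + dt.timedelta(days=t * cfg.scene_period_days)
        if cfg.kind == SNOW_CLASS:
            grid = np.where(values > cfg.value_mean, 200, 25).astype(np.int16)
            n_cloud = int(round(cfg.cloud_fraction * grid.size))
            if n_cloud:
                flat = rng.choice(grid.size, size=n_cloud, replace=False)
                grid.ravel()[flat] = 50
            values = grid
        scenes.append(RasterScene(
            values=values, x0=0.0, y0=0.0, cell_size=cfg.cell_size,
            start_date=start, period_days=cfg.scene_period_days,
            kind=cfg.kind, scene_id=f"{cfg.kind}_{start.isoformat()}",
        ))
    return scenes
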