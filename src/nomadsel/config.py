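"""Pipeline configuration: YAML-backed settings with full validation.

Defaults follow the study design the package implements: pseudo-absence
multipliers 1/2/5/10/20 with the 20x table reported, a 1:1000
used:available weighting, step lags of 1, 5 and 10 days, 25-400
pseudo-steps per stratum with 400 reported, a 20-step minimum per fitted
entity, alpha = 0.05 and 5% availability trims.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .availability import MULTIPLIERS
from .ssf import K_GRID
from .tracks import LAGS


@dataclass
class SimulateSettings:
    n_individuals: int = 6
    n_years: int = 2
    grid_nx: int = 96
    grid_ny: int = 96
    cell_size: float = 250.0
    correlation_length: float = 2000.0
    temporal_persistence: float = 0.6
    beta1: float = 13.0
    beta2: float = -14.0
    n_candidates: int = 30
    step_scale: float = 2000.0
    turn_concentration: float = 1.0
    drop_fraction: float = 0.05


@dataclass
class RSFSettings:
    multipliers: tuple[int, ...] = MULTIPLIERS
    report_multiplier: int = 20
    weight_available: float = 1000.0
    grid_n: int = 10


@dataclass
class SSFSettings:
    lags: tuple[int, ...] = LAGS
    k_values: tuple[int, ...] = K_GRID
    report_k: int = 400
    alpha: float = 0.05
    min_steps: int = 20


@dataclass
class RSSSettings:
    trim: float = 0.05
    n_grid: int = 200


@dataclass
class PipelineConfig:
    outdir: str = "nomadsel_out"
    seed: int = 0
    tracks_path: str | None = None       # external tracks; None = simulated
    scene_index: str | None = None       # external scenes; None = simulated
    boundary_path: str | None = None     # optional GeoJSON study boundary
    growing_start: tuple[int, int] = (5, 9)
    growing_end: tuple[int, int] = (8, 29)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    rsf: RSFSettings = field(default_factory=RSFSettings)
    ssf: SSFSettings = field(default_factory=SSFSettings)
    rss: RSSSettings = field(default_factory=RSSSettings)

    def validate(self) -> None:
        """Raise ValueError listing every offending field at once."""
        problems = []
        for m in self.rsf.multipliers:
            if m not in MULTIPLIERS:
                problems.append(f"rsf.multipliers: {m} not in {MULTIPLIERS}")
        if self.rsf.report_multiplier not in self.rsf.multipliers:
            problems.append("rsf.report_multiplier must be among rsf.multipliers")
        if self.rsf.weight_available <= 0:
            problems.append("rsf.weight_available must be positive")
        for lag in self.ssf.lags:
            if lag not in LAGS:
                problems.append(f"ssf.lags: invalid lag {lag}; allowed {LAGS}")
        for k in self.ssf.k_values:
            if k not in K_GRID:
                problems.append(f"ssf.k_values: {k} not in {K_GRID}")
        if self.ssf.report_k not in self.ssf.k_values:
            problems.append("ssf.report_k must be among ssf.k_values")
        if not (0 < self.ssf.alpha < 1):
            problems.append("ssf.alpha must be in (0, 1)")
        if self.ssf.min_steps < 3:
            problems.append("ssf.min_steps must be >= 3")
        if not (0 <= self.rss.trim < 0.5):
            problems.append("rss.trim must be in [0, 0.5)")
        if self.rss.n_grid < 2:
            problems.append("rss.n_grid must be >= 2")
        if self.simulate.n_individuals < 1:
            problems.append("simulate.n_individuals must be >= 1")
        if self.simulate.n_years < 1:
            problems.append("simulate.n_years must be >= 1")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sub = {"simulate": SimulateSettings, "rsf": RSFSettings,
               "ssf": SSFSettings, "rss": RSSSettings}
        kwargs = {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, value in raw.items():
            if key in sub:
                scls = sub[key]
                sknown = {f.name for f in fields(scls)}
                sunknown = set(value) - sknown
                if sunknown:
                    raise ValueError(
                        f"unknown keys in '{key}': {sorted(sunknown)}")
                for tup in ("multipliers", "lags", "k_values"):
                    if tup in value:
                        value[tup] = tuple(value[tup])
                kwargs[key] = scls(**value)
            elif key in ("growing_start", "growing_end"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
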