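import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nomadsel import LandscapeConfig, generate_scene_series
from nomadsel.scenes import RasterScene
from nomadsel.ssf import StepStratumSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hetero_scenes():
    """Heterogeneous [0, 1] landscape series used by selection tests."""
    cfg = LandscapeConfig(
        grid_nx=128, grid_ny=128, cell_size=250.0, correlation_length=1000.0,
        n_scenes=33, value_mean=0.5, value_sd=0.25, value_min=0.0, value_max=1.0,
        temporal_persistence=0.8, rng_seed=11)
    return generate_scene_series(cfg)


@pytest.fixture
def flat_scene():
    """A single constant greenness scene."""
    return RasterScene(np.full((16, 16), 0.4), 0.0, 0.0, 250.0,
                       dt.date(2015, 5, 9), 16)


def make_strata(z: np.ndarray, **kw) -> StepStratumSet:
    """Wrap a (strata, K+1) covariate matrix; column 0 is observed."""
    z = np.asarray(z, float)
    defaults = dict(K=z.shape[1] - 1, individual_id="t", season="growing",
                    lag_days=1)
    defaults.update(kw)
    return StepStratumSet(z=z, **defaults)


def daily_track_df(xy: np.ndarray, start="2015-05-09") -> pd.DataFrame:
    ts = pd.date_range(start, periods=len(xy), freq="D") + pd.Timedelta(hours=12)
    return pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]})
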