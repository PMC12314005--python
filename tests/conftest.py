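import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermoherd.config import PipelineConfig, TrialWindow
from thermoherd.io_formats import CanopyMap
from thermoherd.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """Two animals, one week per trial, coarse cadence: seconds to generate."""
    return SimConfig(
        seed=7, n_animals=2, label_dt_s=60.0, fixes_per_interval=3,
        trial_windows=[
            TrialWindow(trial_id="trial1", start=dt.date(2022, 11, 21), n_days=7),
            TrialWindow(trial_id="trial2", start=dt.date(2023, 11, 20), n_days=7),
        ],
    )


@pytest.fixture(scope="session")
def tiny_config(tiny_sim_config) -> PipelineConfig:
    return tiny_sim_config.pipeline_config()


@pytest.fixture(scope="session")
def tiny_streams(tiny_sim_config):
    from thermoherd.synthetic_data import generate_all

    return generate_all(tiny_sim_config)


@pytest.fixture
def square_map() -> CanopyMap:
    """100 m-ish square paddock with one square canopy in the SW quadrant."""
    return CanopyMap.from_latlon(
        paddock=[(0.0, 0.0), (0.0, 0.001), (0.001, 0.001), (0.001, 0.0),
                 (0.0, 0.0)],
        canopies=[[(0.0002, 0.0002), (0.0002, 0.0004), (0.0004, 0.0004),
                   (0.0004, 0.0002), (0.0002, 0.0002)]],
    )


def behavior_frame(animal, start, labels, dt_s=5.0):
    """Label stream helper: consecutive dt_s-spaced records."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "animal_id": animal,
        "t": [t0 + pd.Timedelta(seconds=i * dt_s) for i in range(len(labels))],
        "label": labels,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
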