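import dataclasses

import numpy as np
import pytest

from droughtring.ringwidth_io import RingSeries, SeriesCollection
from droughtring.synthetic_data import (DroughtEvent, SimulationConfig, gen_climate,
                                        gen_rings)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def shared_signal_collection(rng):
    """30 series sharing a common year signal with 2:1 signal:noise."""
    n_years = 60
    signal = rng.normal(0, 0.2, n_years)
    series = []
    for i in range(30):
        noise = rng.normal(0, 0.1, n_years)
        rw = 2.0 * np.exp(signal + noise)
        series.append(RingSeries(series_id=f"T{i:02d}", first_year=1960, rw=rw))
    return SeriesCollection(series=series, site_id="S1")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated trial (8 provenances, 1 tree per plot) with its climate."""
    cfg = dataclasses.replace(SimulationConfig(seed=13),
                              n_provenances=8, trees_per_plot=1)
    rng = np.random.default_rng(13)
    climate = gen_climate(cfg, rng)
    collection, truth = gen_rings(cfg, climate, rng)
    return cfg, climate, collection, truth


@pytest.fixture(scope="session")
def single_event_sim():
    """Climate-blind simulation with one imposed 40% drought in 2000.

    beta_climate = 0 so the ring response to the event is only the
    imposed reduction, giving the resilience indices their closed-form
    expectations (resistance ~ 0.6).
    """
    cfg = dataclasses.replace(
        SimulationConfig(seed=99), n_provenances=10, trees_per_plot=2,
        beta_climate=0.0, droughts=(DroughtEvent(2000, (6, 7, 8), 0.6, 0.40),))
    rng = np.random.default_rng(99)
    climate = gen_climate(cfg, rng)
    collection, truth = gen_rings(cfg, climate, rng)
    return cfg, climate, collection, truth
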