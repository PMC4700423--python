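import numpy as np
import pandas as pd
import pytest

from statecortex.core_io import (EventTable, LaminarLFP, Session,
                                 SpikeTrainSet, UnitMeta)
from statecortex.synthetic import SimConfig, simulate_session


def make_events(rows):
    df = pd.DataFrame(rows, columns=list(EventTable.COLUMNS))
    return EventTable(df)


def simple_events():
    """One BF pair plus two clicks in each block kind."""
    rows = [
        (10.0, "bf_on", np.nan, np.nan, "spont", "stim"),
        (11.0, "bf_off", np.nan, np.nan, "spont", "stim"),
        (30.0, "click", 70.0, np.nan, "b1", "no_stim"),
        (33.0, "click", 70.0, np.nan, "b1", "no_stim"),
        (40.0, "bf_on", np.nan, np.nan, "b2", "stim"),
        (41.0, "bf_off", np.nan, np.nan, "b2", "stim"),
        (41.5, "click", 70.0, np.nan, "b2", "stim"),
    ]
    return make_events(rows)


@pytest.fixture
def tiny_session():
    rng = np.random.default_rng(7)
    lfp = LaminarLFP(samples=rng.normal(0, 10, (4, 2000)), fs=1000.0)
    spikes = SpikeTrainSet({0: [0.1, 0.5, 1.2], 1: [0.05, 0.9]})
    units = [
        UnitMeta(unit_id=0, mean_waveform=rng.normal(0, 5, (4, 32)),
                 wave_fs=20000.0, quality=25.0, area="AC"),
        UnitMeta(unit_id=1, mean_waveform=rng.normal(0, 5, (4, 32)),
                 wave_fs=20000.0, quality=30.0, area="MGB"),
    ]
    return Session(lfp=lfp, spikes=spikes, units=units, events=simple_events())


def small_sim_config(**overrides) -> SimConfig:
    """Short session for fast end-to-end tests."""
    base = dict(
        n_ns=3, n_bs1=3, n_bs2=3, n_bs3=3, n_bs4=3, n_mgb=4,
        n_spont_stims=3, spont_period_s=25.0,
        n_click_trials=8, n_trains_per_freq=2,
        recovery_s=12.0, quality_range=(22.0, 40.0),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_session():
    """One small simulated session shared across read-only tests."""
    return simulate_session(small_sim_config(), seed=11)


@pytest.fixture(scope="session")
def default_session():
    """The default-configuration session used for recovery checks."""
    return simulate_session(SimConfig(), seed=5)
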