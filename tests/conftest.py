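import numpy as np
import pytest

import facedecode as fd


@pytest.fixture(scope="session")
def stim_set():
    return fd.build_stimulus_set()


@pytest.fixture(scope="session")
def noise_pseudo(stim_set):
    """Noise-only reduced cohort: 4 participants, 8 channels, 20 timepoints."""
    cfg = fd.CohortConfig(n_participants=4, n_channels=8, tmin=-0.025, tmax=0.075,
                          repetitions=6, seed=11)
    epochs, _ = fd.generate_cohort(cfg, stim_set)
    return fd.bin_average(epochs, bin_size=3, seed=11)


@pytest.fixture(scope="session")
def sex_effect_pseudo(stim_set):
    """Cohort with a strong shared sex pattern from 25 ms to 75 ms."""
    eff = fd.EffectSpec(attribute="sex", onset_ms=25, duration_ms=50, amplitude=2.0)
    cfg = fd.CohortConfig(n_participants=4, n_channels=8, tmin=-0.025, tmax=0.1,
                          repetitions=6, effects=[eff], seed=12)
    epochs, _ = fd.generate_cohort(cfg, stim_set)
    return fd.bin_average(epochs, bin_size=3, seed=12)


@pytest.fixture(scope="session")
def responded_tables(stim_set):
    """Two participants' filled trial tables from a high-accuracy responder."""
    acc = {e: 0.95 for e in fd.design.EXPRESSIONS}
    rt = {"happy": (0.63, 0.08), "angry": (0.66, 0.08),
          "sad": (0.67, 0.09), "neutral": (0.64, 0.08)}
    tables = []
    for p in range(4):
        tt = fd.schedule_session(stim_set, repetitions=12, seed=100 + p)
        tables.append(fd.simulate_responder(tt, acc, rt, seed=200 + p))
    return tables


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
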