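"""Shared fixtures; heavy synthetic batches are session-scoped."""

import numpy as np
import pytest

from fwavetilt.synthetic import (FWaveGenParams, PhaseSpec, VentricularGenParams,
                                 generate_phase_recording, table2_scenario,
                                 generate_tilt_recording)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def short_tilt():
    """A six-phase record with 30-s phases (fast preprocessing fixture)."""
    scenario = table2_scenario(seed=11, durations=(30.0,) * 6)
    record, truth = generate_tilt_recording(scenario)
    return record, truth


@pytest.fixture(scope="session")
def medium_tilt():
    """A six-phase record with 60-s phases, long enough for all metrics."""
    scenario = table2_scenario(seed=4, durations=(60.0,) * 6)
    record, truth = generate_tilt_recording(scenario)
    return record, truth


@pytest.fixture(scope="session")
def single_phase():
    """One 3-minute single-phase record at the default study conditions."""
    phase = PhaseSpec("B1", 180.0,
                      fwave=FWaveGenParams(ff_mean=6.7, mod_amplitude=0.077,
                                           resp_rate=0.14),
                      ventricular=VentricularGenParams())
    record, truth = generate_phase_recording(phase, seed=5)
    return record, truth


@pytest.fixture(scope="session")
def recovery20():
    """The 20-seed calibrated end-to-end recovery batch."""
    from fwavetilt.experiments import recovery_batch

    return recovery_batch(n_seeds=20, base_seed=0)


@pytest.fixture(scope="session")
def sweep20():
    """Modulation sweep, 20 seeds per injected amplitude."""
    from fwavetilt.experiments import modulation_sweep

    return modulation_sweep(mod_amplitudes=(0.0, 0.025, 0.05, 0.08, 0.1),
                            n_seeds=20, base_seed=0)
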