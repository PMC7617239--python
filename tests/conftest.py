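"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from flickersync import synthgen


@pytest.fixture(scope="session")
def flicker_40hz():
    """A 40 Hz flicker block: (stimulus, trials)."""
    protocol = synthgen.FlickerProtocol(frequency=40.0, n_trials=20)
    return synthgen.make_flicker(protocol, seed=101)


@pytest.fixture(scope="session")
def locked_train_40hz(flicker_40hz):
    """A strongly 40 Hz-locked unit on the shared flicker block."""
    stim, trials = flicker_40hz
    spec = synthgen.LockedTrainSpec(base_rate=20.0, mod_depth=0.8, seed=7)
    return synthgen.simulate_locked_train(spec, trials, 40.0, unit_id=0)


@pytest.fixture(scope="session")
def waveform_benchmark():
    """400-unit separable broad/narrow benchmark: (entries, truth labels)."""
    from flickersync import celltypes

    broad = synthgen.simulate_waveforms("broad", 200, seed=11)
    narrow = synthgen.simulate_waveforms("narrow", 200, seed=12)
    wfs = np.vstack([broad.waveforms, narrow.waveforms])
    entries = [celltypes.mean_waveform(w, unit_id=i) for i, w in enumerate(wfs)]
    truth = np.array(["broad"] * 200 + ["narrow"] * 200, dtype=object)
    return entries, truth
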