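import numpy as np
import pytest

from cgam.simulate import NoiseSpec, SyntheticTrialConfig, generate_waveform_trial


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial + ground truth, shared across tests."""
    cfg = SyntheticTrialConfig(seed=7)
    return generate_waveform_trial(cfg)


@pytest.fixture(scope="session")
def quiet_trial():
    """Symmetric, noise-free trial (the null case)."""
    cfg = SyntheticTrialConfig(seed=7, noise=NoiseSpec(0, 0, 0, 0, 0))
    return generate_waveform_trial(cfg)


def match_truth(extracted, truth, param, side_suffix):
    """Align extracted step values to ground-truth records by heel-strike time
    and return the absolute errors."""
    t_ext = extracted["t_hs" + side_suffix].to_numpy()
    t_tru = truth["t_hs" + side_suffix].to_numpy()
    idx = np.argmin(np.abs(t_ext[:, None] - t_tru[None, :]), axis=1)
    assert np.abs(t_ext - t_tru[idx]).max() < 2e-3, "step alignment failed"
    return np.abs(extracted[param + side_suffix].to_numpy()
                  - truth[param + side_suffix].to_numpy()[idx])
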