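import pytest

import murisleep as ms


@pytest.fixture(scope="session")
def default_cfg():
    """Default study conditions, shortened to 4 h for unit-level tests."""
    return ms.SimConfig(seed=101, hours=4)


@pytest.fixture(scope="session")
def short_labelled(default_cfg):
    """One 4-h labelled recording at default SNR."""
    hyp = ms.sample_hypnogram(default_cfg)
    return ms.synthesize_signals(hyp, default_cfg)


@pytest.fixture(scope="session")
def short_staged(short_labelled, default_cfg):
    """(predicted hypnogram, thresholds, features) for the 4-h recording."""
    return ms.stage_recording(
        short_labelled.recording, schedule=default_cfg.schedule
    )
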