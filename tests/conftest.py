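import numpy as np
import pytest

from accdetect import ParticipantProfile, make_design


@pytest.fixture(scope="session")
def design():
    """The default recording design (2048 Hz, 6 SNRs x 2 frequencies x 2 reps)."""
    return make_design()


@pytest.fixture(scope="session")
def fast_design():
    """Same timing grid at a lower rate / fewer sweeps, for Monte-Carlo tests."""
    return make_design(fs=512.0, sweeps=40)


@pytest.fixture()
def quiet_profile():
    """Deterministic participant: no noise, jitter or artifacts."""
    return ParticipantProfile(
        latency_jitter_ms=0.0, noise_rms_uv=0.0, artifact_rate=0.0
    )


@pytest.fixture()
def noise_only_profile():
    """Participant with no evoked response at any SNR."""
    return ParticipantProfile(
        acc_amp_at_max_snr_uv={1000.0: 0.0, 4000.0: 0.0}, artifact_rate=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
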