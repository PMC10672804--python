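import numpy as np
import pytest

from sospin import GeneratorConfig, generate_recording
from sospin.recording import Recording


@pytest.fixture(scope="session")
def default_recording():
    """One rendered 10-min recording with ground truth, shared read-only."""
    cfg = GeneratorConfig(duration_s=600.0, seed=11)
    rec, gt = generate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture()
def quiet_recording():
    """Low-noise recording factory for constructed-signal tests."""

    def build(signal, fs=256.0, labels=("C3", "Cz", "C4", "Pz"), stage="N2", artifact_sec=()):
        signal = np.atleast_2d(signal)
        if signal.shape[0] == 1 and len(labels) > 1:
            signal = np.tile(signal, (len(labels), 1))
        n_sec = int(np.ceil(signal.shape[1] / fs))
        n_epochs = int(np.ceil(n_sec / 30))
        mask = np.zeros((signal.shape[0], n_sec), bool)
        for s in artifact_sec:
            mask[:, s] = True
        return Recording(
            signal=signal,
            sampling_rate_hz=fs,
            channel_labels=labels[: signal.shape[0]],
            hypnogram=np.array([stage] * n_epochs, object),
            artifact_mask=mask,
        )

    return build
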