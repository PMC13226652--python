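import numpy as np
import pytest

from magcardia.fieldsim import NoiseSpec, PatientSpec, simulate_recording
from magcardia.preprocess import preprocess_pipeline


@pytest.fixture(scope="session")
def clean_recording():
    """One minute of noise-free control simulation with ground-truth R peaks."""
    spec = PatientSpec(patient_id="clean", minutes=1.0, morph_variability=0.0,
                       noise=NoiseSpec(white_sigma=0.0, drift_amplitude=0.0,
                                       line_amplitude=0.0, missing_channel_prob=0.0))
    return simulate_recording(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_recording():
    """Half a minute of control simulation at the default noise levels."""
    spec = PatientSpec(patient_id="noisy", minutes=0.5)
    return simulate_recording(spec, seed=13)


@pytest.fixture(scope="session")
def preprocessed_segments(noisy_recording):
    return preprocess_pipeline(noisy_recording)


@pytest.fixture(scope="session")
def segment(preprocessed_segments):
    return preprocessed_segments[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
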