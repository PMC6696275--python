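import numpy as np
import pytest

from earforce import SubjectParams, generate_session, preset_subjects


@pytest.fixture(scope="session")
def presets():
    return preset_subjects()


@pytest.fixture(scope="session")
def session_a(presets):
    """One default synthetic session (subject-A analogue)."""
    return generate_session(presets["A"], subject_id="A")


@pytest.fixture(scope="session")
def ideal_params():
    """Zero-noise, unquantized parameters: exact affine coupling."""
    return SubjectParams(
        slope=-16.1,
        noise_ear_sd=0.0,
        noise_emg_sd=0.0,
        noise_force_sd=0.0,
        drift_sd=0.0,
        peak_jitter=0.0,
        quantize=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def ideal_session(ideal_params):
    return generate_session(ideal_params, subject_id="ideal")


@pytest.fixture
def rng():
    return np.random.default_rng(20190806)
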