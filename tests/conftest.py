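import numpy as np
import pytest
from hypothesis import settings

from seizkd.preprocess import WindowingSpec
from seizkd.student import StudentConfig, StudentModel
from seizkd.synthetic import SynthConfig, generate_recording

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def short_cfg():
    """Small single-seizure recording config used across module tests."""
    return SynthConfig(n_channels=4, duration=600.0, preictal_len=120.0,
                       seizure_schedule=((400.0, 430.0),), seed=7)


@pytest.fixture(scope="session")
def short_recording(short_cfg):
    return generate_recording(short_cfg)


@pytest.fixture(scope="session")
def short_windowing():
    return WindowingSpec(preictal_len=120.0, interictal_gap=120.0,
                         merge_gap=120.0, sph=30.0, sop=120.0)


@pytest.fixture(scope="session")
def student():
    """One default student instance shared by inference-only tests."""
    return StudentModel(StudentConfig(), seed=0)


@pytest.fixture(scope="session")
def random_windows():
    rng = np.random.default_rng(42)
    return rng.normal(size=(8, 22, 512)).astype(np.float32)
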