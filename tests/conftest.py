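import numpy as np
import pytest

from swdkit.design import SessionDesign
from swdkit.synth import SessionConfig, assemble_session


@pytest.fixture(scope="session")
def small_design() -> SessionDesign:
    """Scaled-down protocol: two 10-min control + six 10-min treatment epochs."""
    return SessionDesign(control_start_s=-1200.0, treatment_end_s=3600.0, epoch_length_s=600.0)


@pytest.fixture(scope="session")
def small_config(small_design) -> SessionConfig:
    return SessionConfig(
        design=small_design,
        fs=256.0,
        sleep_bout_offset_s=420.0,
        sleep_bout_len_s=90.0,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    """One synthesized animal-session shared by read-only tests."""
    return assemble_session(small_config, 12345)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
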