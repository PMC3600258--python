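import numpy as np
import pytest
from hypothesis import settings

from tpmtyper import SimParams, default_panel

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def noise_free_params():
    """Ideal assay: no Ct/fluorescence noise, every copy detected."""
    return SimParams(
        ct_noise_sd=0.0,
        ipc_ct_sd=0.0,
        fluor_noise_sd=0.0,
        detection_eff=1.0,
        detection_eff_by_snp={},
    )
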