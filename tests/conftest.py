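import numpy as np
import pytest

from wsidiag import SynthConfig, generate_scan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scan_bundle():
    """One deterministic synthetic scan: (pyramid, annotations, truth mask)."""
    return generate_scan(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def training_scans():
    """Six synthetic scans used by classification tests (first four train)."""
    return [generate_scan(SynthConfig(seed=s)) for s in range(6)]
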