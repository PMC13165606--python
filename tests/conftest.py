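import numpy as np
import pytest

from hemignn import SynthSpec, generate_cohort, standard_1020_montage


@pytest.fixture(scope="session")
def montage():
    return standard_1020_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two pairs, 8 s recordings: enough for I/O and plumbing tests."""
    spec = SynthSpec(n_pairs=2, duration=8.0, seed=7)
    manifest, recordings = generate_cohort(spec)
    return spec, manifest, recordings
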