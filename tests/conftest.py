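import numpy as np
import pytest

import qclreg as q


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic QSPR table: 86 x 10, 4 latent factors."""
    return q.generate()


@pytest.fixture(scope="session")
def noisefree_dataset():
    return q.generate(q.GeneratorSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def mera():
    return q.build_mera_ansatz()


@pytest.fixture(scope="session")
def encoded_default(default_dataset):
    pre = q.fit_preprocessor(default_dataset, 4)
    return q.EncodedDataset(
        pre.transform_x(default_dataset.X), pre.transform_y(default_dataset.y)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
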