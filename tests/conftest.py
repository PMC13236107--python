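import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def separable_blobs():
    """The well-separated blob configuration: centers (0.3,1.0)/(1.0,0.3),
    sigma=0.3, 100 samples, min-max scaled to [0,1]."""
    from qensemble.synthdata import BlobConfig, make_blob_dataset

    return make_blob_dataset(BlobConfig(cluster_std=0.3, p1=0.3, p2=1.0, seed=7))
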