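import numpy as np
import pytest

from gald.datasets import FixtureSpec, make_blobs_with_outliers
from gald.gan import GANConfig
from gald.scoring import fit


@pytest.fixture(scope="session")
def blob_model():
    """Detector fitted once on a single compact normal cluster (no anomalies)."""
    data = make_blobs_with_outliers(
        FixtureSpec(n_normal=300, n_anomaly=0, d=2, n_clusters=1, seed=0)
    )
    model = fit(data, GANConfig(seed=0), k=10)
    return data, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
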