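import numpy as np
import pytest

from cytopac.io_prep import EventMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs(rng):
    """Two well-separated spherical Gaussians in 3-D with labels."""
    a = rng.normal(0.0, 1.0, size=(500, 3))
    b = rng.normal(8.0, 1.0, size=(500, 3))
    values = np.vstack([a, b])
    labels = np.repeat([0, 1], 500)
    order = rng.permutation(1000)
    m = EventMatrix(
        values=values[order],
        marker_names=["m1", "m2", "m3"],
        sample_id="blobs",
        transformed=True,
    )
    return m, labels[order]


def make_matrix(values, sample_id="s", transformed=True):
    values = np.asarray(values, dtype=float)
    return EventMatrix(
        values=values,
        marker_names=[f"V{i + 1}" for i in range(values.shape[1])],
        sample_id=sample_id,
        transformed=transformed,
    )
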