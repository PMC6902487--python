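import numpy as np
import pytest

from cytogate import EventTable, MixtureModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_component_model():
    """A hand-written, well-separated 2-component mixture on channel scale."""
    return MixtureModel(
        weights=np.array([0.7, 0.3]),
        means=np.array([[10000.0, 20000.0], [45000.0, 50000.0]]),
        covariances=np.array(
            [
                [[1.0e6, 2.0e5], [2.0e5, 8.0e5]],
                [[2.5e6, -4.0e5], [-4.0e5, 1.5e6]],
            ]
        ),
        channel_names=("FSC", "DAPI"),
    )


@pytest.fixture
def five_events():
    return EventTable(
        np.array(
            [
                [10500.0, 19800.0],
                [44800.0, 50500.0],
                [9000.0, 21000.0],
                [30000.0, 35000.0],
                [46000.0, 49000.0],
            ]
        ),
        ("FSC", "DAPI"),
    )
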