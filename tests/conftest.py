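import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from funconn.atlas import AtlasDefinition, make_default_atlas
from funconn.synthetic import TimeSeriesMatrix


@pytest.fixture(scope="session")
def default_atlas():
    return make_default_atlas()


@pytest.fixture
def toy_atlas():
    return AtlasDefinition(
        labels=("N1", "N2", "N3"),
        centroids=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0],
                            [0.0, 0.0, 10.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260301)


def make_series(values, tr=3.0, subject_id="S001", group="A"):
    values = np.asarray(values, float)
    labels = tuple(f"R{k:02d}" for k in range(values.shape[1]))
    return TimeSeriesMatrix(subject_id=subject_id, group_label=group,
                            values=values, tr_seconds=tr,
                            region_labels=labels)
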