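import numpy as np
import pytest

from stridemap import (
    ActivityClass,
    GaitGeneratorParams,
    LocalFrame,
    PathRecord,
    generate_labeled_dataset,
    train_classifier,
)
from stridemap.synthetic import BASE_LAT, BASE_LON


@pytest.fixture(scope="session")
def frame():
    """Metric frame anchored at the synthetic networks' reference point."""
    return LocalFrame(BASE_LON, BASE_LAT)


@pytest.fixture(scope="session")
def mkpath(frame):
    """Factory turning metre coordinates into a PathRecord in WGS84."""

    def factory(xy, **kwargs):
        return PathRecord(geometry=frame.to_lonlat(np.asarray(xy, dtype=float)), **kwargs)

    return factory


@pytest.fixture(scope="session")
def small_dataset():
    """Labeled strides from 5 synthetic subjects (fixed seed)."""
    return generate_labeled_dataset(n_subjects=5, params=GaitGeneratorParams(seed=123))


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    return train_classifier(small_dataset, model_kind="svm_ovr", seed=0)
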