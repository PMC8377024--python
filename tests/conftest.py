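import numpy as np
import pytest

from cytopoint.annotations import (
    CELL_CLASSES,
    AnnotationSet,
    CentreAnnotation,
    ClassConfig,
    default_class_configs,
)


@pytest.fixture
def classes():
    return default_class_configs()


@pytest.fixture
def sharp_classes():
    """Class configs with small sigma so decoded peaks are tight."""
    return [ClassConfig(c, 12.0, 1.5) for c in CELL_CLASSES]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(points, tile_id="t0", size=256, assessor="truth"):
    """Build an AnnotationSet from (x, y, cell_class) triples."""
    s = AnnotationSet(tile_id, size, size)
    for x, y, c in points:
        s.add(CentreAnnotation(tile_id, float(x), float(y), c, assessor))
    return s


@pytest.fixture
def make_annotations():
    return make_set
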