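import numpy as np
import pytest

from kennelmot.core import BoundingBox, Detection, TrackerConfig


@pytest.fixture
def config():
    return TrackerConfig()


def make_box(x=0.0, y=0.0, w=10.0, h=10.0):
    return BoundingBox(x, y, w, h)


def make_det(camera="cam0", frame=0, box=None, det_conf=0.9,
             id_conf=None, identities=("R-N", "Y-St", "B-Sq")):
    if box is None:
        box = make_box()
    if id_conf is None:
        id_conf = {i: 1.0 / len(identities) for i in identities}
    elif not isinstance(id_conf, dict):
        id_conf = dict(zip(identities, id_conf))
    return Detection(camera, frame, box, det_conf, id_conf)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
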