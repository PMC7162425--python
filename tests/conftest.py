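import numpy as np
import pytest

from toposmlm import DetectionTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_csv(tmp_path):
    p = tmp_path / "detections.csv"
    p.write_text(
        "x [nm],y [nm],frame,intensity [photon],uncertainty [nm],extra\n"
        "100.0,200.0,1,1200,15.0,a\n"
        "110.0,210.0,2,900,18.0,b\n"
        "400.0,500.0,7,2500,9.0,c\n"
    )
    return p


def make_table(coords, **kw):
    return DetectionTable.from_arrays(np.asarray(coords, dtype=float), **kw)
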