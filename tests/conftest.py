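import numpy as np
import pytest

from retquant.layers import LAYERS
from retquant.records import ChannelImage, ImageRecord
from retquant.synthetic import make_layer_geometry


@pytest.fixture
def tiling_mask():
    """60x10 exact tiling: each of the six layers is exactly 100 px."""
    return make_layer_geometry(60, 10, {lay: 10 for lay in LAYERS})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_record(mask, channels=None, cohort="TUBB3", **kwargs):
    """Assemble a minimal valid ImageRecord around a layer mask."""
    if channels is None:
        channels = {
            "amyloid": np.zeros(mask.shape, dtype=np.uint16),
            "marker": np.zeros(mask.shape, dtype=np.uint16),
        }
    defaults = dict(donor_id="D1", group="AD", region="central", cohort=cohort,
                    section=1, image=1)
    defaults.update(kwargs)
    return ImageRecord(
        mask=mask,
        channels={r: ChannelImage(data=np.asarray(d), role=r) for r, d in channels.items()},
        **defaults,
    )


@pytest.fixture
def record_factory():
    return build_record
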