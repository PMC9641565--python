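import numpy as np
import pytest

from roifinder.io import ElementalMapSet, ScanMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_map_set(channels: dict, scan_id="test", pixel_step=0.25,
                 dwell_time=100.0, origin=(0.0, 0.0)) -> ElementalMapSet:
    shape = next(iter(channels.values())).shape
    md = ScanMetadata(scan_id=scan_id, pixel_step=pixel_step,
                      dwell_time=dwell_time, origin=origin, shape=shape)
    return ElementalMapSet(metadata=md, channels=channels)


@pytest.fixture
def map_set_factory():
    return make_map_set


@pytest.fixture
def random_map_set(rng):
    """3-channel 32x32 scan with random non-negative counts."""
    channels = {el: rng.uniform(0, 50, size=(32, 32)) for el in ("K", "P", "Ca")}
    return make_map_set(channels)
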