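import numpy as np
import pytest

import ctcscan as cs
from ctcscan import segmentation


@pytest.fixture(scope="session")
def small_config():
    """Compact noise-free scene used by several modules."""
    return cs.SimulationConfig(image_height_px=420, image_width_px=420,
                               n_background_cells=30)


@pytest.fixture(scope="session")
def small_scan(small_config):
    return cs.simulate_scan(small_config, seed=1234)


@pytest.fixture(scope="session")
def segmented_small_scan(small_scan, small_config):
    scan, truth = small_scan
    labels, regions = segmentation.segment_dapi(
        scan.channels["DAPI"], small_config.pixel_size_um)
    return scan, truth, labels, regions


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
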