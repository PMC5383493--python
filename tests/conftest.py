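import numpy as np
import pytest

from burnsel import synth
from burnsel.grid import CategoricalRaster, RasterGrid


@pytest.fixture(scope="session")
def tripod_stack():
    """Small but fully featured synthetic study area, shared across tests."""
    cfg = synth.preset("tripod", seed=7, shape=(150, 150))
    return synth.build_landscape(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(values, cell_size=30.0, nodata=None, origin=(0.0, 0.0)):
    return RasterGrid(np.asarray(values, dtype=float), cell_size=cell_size,
                      origin=origin, nodata=nodata)


def make_cat(values, legend, cell_size=30.0, nodata=None):
    return CategoricalRaster(np.asarray(values, dtype=np.int16), cell_size=cell_size,
                             nodata=nodata, legend=legend)
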