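import numpy as np
import pytest
from shapely.geometry import box

import leriscape as L


@pytest.fixture(scope="session")
def square_extent():
    return (0.0, 0.0, 100.0, 100.0)


@pytest.fixture(scope="session")
def square_boundary(square_extent):
    return box(*square_extent)


@pytest.fixture(scope="session")
def synth_config():
    return L.SynthConfig(seed=42, clumping=0.5, urban_rate=0.3)


@pytest.fixture(scope="session")
def landcover(synth_config, square_extent, square_boundary):
    return L.generate_landcover(synth_config, square_extent, 1.0, square_boundary)


@pytest.fixture(scope="session")
def indicators(synth_config, square_extent, square_boundary):
    return L.generate_indicators(synth_config, square_extent, 1.0, square_boundary)


@pytest.fixture(scope="session")
def grid(square_boundary):
    return L.build_fishnet(square_boundary, 20.0)


@pytest.fixture(scope="session")
def study(synth_config, square_extent, square_boundary, landcover, indicators):
    """Five-period synthetic study assessed end to end (in memory)."""
    years = [2000, 2005, 2010, 2015, 2020]
    seq = [landcover] + L.evolve_landcover(landcover, synth_config, steps=4)
    landcovers = dict(zip(years, seq))
    cfg = L.RunConfig(years=years, cell_size=20.0, seed=synth_config.seed)
    return L.assess(landcovers, indicators, square_boundary, cfg)


def toy_raster(data, pixel_size=1.0, origin=(0.0, 0.0), nodata=0):
    return L.Raster(np.asarray(data, dtype=np.int16), origin=origin,
                    pixel_size=pixel_size, nodata=nodata)
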