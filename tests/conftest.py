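import numpy as np
import pandas as pd
import pytest

from invaniche.raster import GridRaster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_raster():
    """5x5 raster, 1 km cells, origin at (0, 0)."""
    vals = np.arange(25, dtype=float).reshape(5, 5)
    return GridRaster(vals, cell_km=1.0)


@pytest.fixture
def gaussian_sample(rng):
    """A well-conditioned multivariate sample for selection tests."""
    n = 2000
    z = rng.standard_normal((n, 4))
    df = pd.DataFrame(
        {
            "v1": z[:, 0],
            "v2": 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1],  # r = 0.9 with v1
            "v3": z[:, 2],
            "v4": z[:, 3],
        }
    )
    return df
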