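import datetime as dt

import numpy as np
import pytest

from hmssi import (
    BandMap,
    GridGeometry,
    GrowthStage,
    ReflectanceScene,
    default_campaign_config,
    generate_campaign,
)


def make_geom(rows=6, cols=8, res=10.0, x0=500000.0, y0=3000000.0):
    return GridGeometry(rows=rows, cols=cols, x0=x0, y0=y0, resolution=res)


def make_scene(bands=None, geom=None, rows=6, cols=8, date=dt.date(2017, 7, 12),
               stage=GrowthStage.BOOTING, mask=None, res=10.0):
    """A small 5-band reflectance scene with plausible rice-canopy values."""
    geom = geom or make_geom(rows, cols, res=res)
    if bands is None:
        base = np.array([0.04, 0.08, 0.05, 0.42, 0.30])  # B2 B4 B5 B6 B7
        bands = np.tile(base[:, None, None], (1, geom.rows, geom.cols))
    if mask is None:
        mask = np.zeros(geom.shape, dtype=bool)
    return ReflectanceScene(
        bands=bands, geom=geom, band_map=BandMap.sentinel2(),
        acquisition_date=date, growth_stage=stage, nodata_mask=mask,
    )


def random_scene(rng, rows=6, cols=8, **kwargs):
    """Random reflectance in [0.01, 0.6] on all five bands."""
    bands = rng.uniform(0.01, 0.6, size=(5, rows, cols))
    return make_scene(bands=bands, rows=rows, cols=cols, **kwargs)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic campaign shared across tests."""
    return generate_campaign(default_campaign_config(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
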