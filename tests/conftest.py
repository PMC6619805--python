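import datetime

import numpy as np
import pandas as pd
import pytest

from bsevalue import BSERecord, SiteGrid

EPOCH = datetime.date(2024, 1, 1)


@pytest.fixture
def small_grid():
    """5x5 grid of 100 m cells."""
    return SiteGrid(origin_x=0.0, origin_y=0.0, cell_size=100.0, n_x=5, n_y=5)


@pytest.fixture
def record_factory(small_grid):
    """Build a BSE at a given site's center on a given day offset."""
    counter = {"n": 0}

    def make(site_id: str, day: int, species="SP1", observer="observer_00", grid=None):
        g = grid or small_grid
        ix, iy = g.parse_site_id(site_id)
        cx = g.origin_x + (ix + 0.5) * g.cell_size
        cy = g.origin_y + (iy + 0.5) * g.cell_size
        lon, lat = g.projection.to_lonlat(cx, cy)
        counter["n"] += 1
        date = EPOCH + datetime.timedelta(days=day)
        return BSERecord(
            observation_id=f"t{counter['n']:05d}",
            lon=float(lon),
            lat=float(lat),
            timestamp=pd.Timestamp(f"{date.isoformat()}T12:00:00Z"),
            species_code=species,
            observer_id=observer,
            site_id=site_id,
        )

    return make


def day_ordinal(day_offset: int) -> int:
    return (EPOCH + datetime.timedelta(days=day_offset)).toordinal()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
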