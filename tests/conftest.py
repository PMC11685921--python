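import numpy as np
import pandas as pd
import pytest

from driftome.envfields import GridField


@pytest.fixture
def constant_field():
    """Constant 12 degC field over a small box."""
    lats = np.linspace(-46.0, -42.0, 5)
    lons = np.linspace(167.0, 175.0, 9)
    times = np.arange(0.0, 30.0)
    return GridField(
        lats=lats, lons=lons, times=times,
        values=np.full((len(times), len(lats), len(lons)), 12.0),
    )


@pytest.fixture
def linear_field():
    """Field linear in lat/lon, constant in time: v = 2*(lat+44) + (lon-170)."""
    lats = np.linspace(-46.0, -42.0, 5)
    lons = np.linspace(167.0, 175.0, 9)
    times = np.arange(0.0, 10.0)
    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    sl = 2.0 * (LA + 44.0) + (LO - 170.0)
    return GridField(
        lats=lats, lons=lons, times=times,
        values=np.broadcast_to(sl, (len(times),) + sl.shape).copy(),
    )


@pytest.fixture
def daily_ramp_field():
    """Field equal to (time+1) everywhere: value 1..30 on days 0..29."""
    lats = np.linspace(-46.0, -42.0, 3)
    lons = np.linspace(167.0, 175.0, 3)
    times = np.arange(0.0, 30.0)
    vals = np.broadcast_to(
        (times + 1.0)[:, None, None], (len(times), 3, 3)
    ).copy()
    return GridField(lats=lats, lons=lons, times=times, values=vals)


def toy_community(counts: dict, status: dict, taxonomy: dict | None = None,
                  population: dict | None = None):
    """Build a CommunityTable from plain dicts (helper for tests)."""
    from driftome.community import CommunityTable

    counts_df = pd.DataFrame.from_dict(counts, orient="index")
    meta = pd.DataFrame({"status": pd.Series(status)})
    if population is not None:
        meta["population"] = pd.Series(population)
    tax = pd.Series(taxonomy) if taxonomy else None
    return CommunityTable(counts=counts_df, metadata=meta, taxonomy=tax)
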