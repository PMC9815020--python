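import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from carescape import (IndicatorPanel, INDICATOR_IDS, SpatialWeights,
                       SyntheticConfig, generate_city_map)
from carescape.indicators import by_id


def make_panel(n_cities=2, years=(2010, 2011, 2012), seed=0,
               missing_at=()) -> IndicatorPanel:
    """Small valid panel: deterministic values, optional missing cells."""
    rng = np.random.default_rng(seed)
    rows = []
    regions = ["Eastern", "Western", "Central", "Northeast"]
    for c in range(n_cities):
        city = f"X{c:02d}"
        region = regions[c % 4]
        for area in ("urban", "rural"):
            for year in years:
                for ind in INDICATOR_IDS:
                    if by_id(ind).kind == "proportion":
                        val = float(rng.uniform(5, 60))
                    else:
                        val = float(rng.uniform(10, 1000))
                    if (city, area, year, ind) in missing_at:
                        val = np.nan
                    rows.append((city, region, area, year, ind, val))
    df = pd.DataFrame(rows, columns=["city_id", "region", "area", "year",
                                     "indicator", "value"])
    return IndicatorPanel.from_dataframe(df)


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture
def city_map():
    """60-city synthetic map for spatial tests."""
    return generate_city_map(SyntheticConfig(seed=5, n_cities=60))


def weights_from_dense(dense, row_standardized=False) -> SpatialWeights:
    n = len(dense)
    return SpatialWeights(ids=[f"C{i}" for i in range(n)],
                          matrix=sp.csr_matrix(np.asarray(dense, dtype=float)),
                          row_standardized=row_standardized)
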