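import numpy as np
import pandas as pd
import pytest

import heatslope as hs


@pytest.fixture(scope="session")
def study():
    """A small two-warm-season study shared by design/model tests."""
    areas = hs.gen_area_frame(12, seed=1)
    weather = hs.gen_weather("2007-06-01", "2009-09-30", seed=7)
    calendar = hs.gen_holiday_calendar(range(2007, 2010))
    design = hs.temporal_design(weather["date"], calendar)
    exposure = hs.lagged_exposure(weather)
    basis = hs.spatial_basis(areas)
    return {
        "areas": areas,
        "weather": weather,
        "calendar": calendar,
        "design": design,
        "exposure": exposure,
        "basis": basis,
    }


@pytest.fixture(scope="session")
def quick_mcmc():
    """Shortened MCMC settings for fast posterior checks."""
    return hs.McmcSettings(burn_in=600, samples=600, chains=2, seed=11)


def single_area_frame(population=1_000_000.0):
    """A one-area frame for citywide-style simulations."""
    return pd.DataFrame(
        {
            "area_id": ["SLA001"],
            "population": [population],
            "centroid_ew": [0.5],
            "centroid_ns": [0.5],
            "pop_density": [1500.0],
            "pct_high_income": [6.0],
            "pct_over65": [13.0],
            "pct_low_income": [12.0],
        }
    )
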