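"""Shared fixtures: small synthetic worlds and toy schedules."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from grazerange.synthetic import generate_landscape
from grazerange.temporal import GrazingSchedule


@pytest.fixture(scope="session")
def landscape():
    """Small co-registered cover/NDVI rasters (2 x 2 km, 20 m cells)."""
    return generate_landscape((0.0, 0.0, 2000.0, 2000.0), 20.0, seed=7,
                              smoothness=200.0)


@pytest.fixture(scope="session")
def toy_schedule() -> GrazingSchedule:
    """One 60-day summer term and one 25-day December term, one site group."""
    site = box(800.0, 800.0, 1200.0, 1200.0)
    intervals = pd.DataFrame({
        "site_id": ["s1", "s1"],
        "group": ["south", "south"],
        "start": [dt.date(2017, 6, 10), dt.date(2016, 12, 1)],
        "end": [dt.date(2017, 8, 8), dt.date(2016, 12, 25)],
    })
    return GrazingSchedule(intervals, {"s1": site}, {"s1": "south"})


@pytest.fixture(scope="session")
def clustered_logit_data():
    """Binary data with a known random-intercept structure (50 x 200)."""
    rng = np.random.default_rng(42)
    G, n = 50, 200
    sd = 1.0
    u = rng.normal(0.0, sd, G)
    X = np.column_stack([np.ones(G * n), rng.standard_normal((G * n, 2))])
    g = np.repeat(np.arange(G), n)
    from scipy.special import expit

    beta = np.array([-1.0, 0.8, -0.5])
    y = (rng.random(G * n) < expit(X @ beta + u[g])).astype(float)
    Xdf = pd.DataFrame(X, columns=["(Intercept)", "x1", "x2"])
    return {"X": Xdf, "y": y, "groups": g, "beta": beta, "re_sd": sd}
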