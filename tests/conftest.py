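"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from abrolhos.hurdle_sdm import HurdleSpec
from abrolhos.synthetic_data import (SimConfig, simulate_covariates,
                                     simulate_surveys)


@pytest.fixture(scope="session")
def recovery_config():
    """Continuous-mode config, field and observer off: well-specified
    likelihood, 500 juvenile censuses, for parameter-recovery tests."""
    return SimConfig(
        sites_per_location=(4, 4, 4, 4, 5, 4),   # 25 sites
        censuses_per_site_year=20,               # -> n = 500 per stage
        years=(2003,), late_start_locations=(),
        beta_bin={"intercept": -0.5, "rugosity": 0.8, "depth_m": -0.5,
                  "cca": 0.4},
        beta_gam={"intercept": -1.9, "rugosity": 0.4, "depth_m": -0.3,
                  "cca": 0.25},
        year_effects={}, observer_sd=0.0, spatial=None, mode="continuous")


@pytest.fixture(scope="session")
def recovery_spec():
    return HurdleSpec(terms=("rugosity", "depth_m", "cca"),
                      include_observer_effect=False,
                      include_year_factor=False,
                      include_spatial_field=False)


@pytest.fixture(scope="session")
def recovery_data(recovery_config):
    cov = simulate_covariates(recovery_config, 11)
    rec, truth = simulate_surveys(recovery_config, cov, 11)
    return rec, cov, truth


@pytest.fixture()
def tiny_surveys():
    """Hand-built survey table: 2 sites, 2 observers, juveniles only."""
    rows = []
    for i, (site, count) in enumerate([("A-01", 0), ("A-01", 3),
                                       ("B-01", 1), ("B-01", 0)]):
        rows.append({"site_id": site, "location": site.split("-")[0],
                     "mpa_regime": "no-take", "year": 2003 + i % 2,
                     "observer_id": f"obs{i % 2 + 1}",
                     "life_stage": "juvenile", "radius_m": 2.0,
                     "count": count})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20030101)
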