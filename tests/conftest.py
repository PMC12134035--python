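import numpy as np
import pandas as pd
import pytest

from dormouse_torpor import data_model as dm
from dormouse_torpor import synthetic_data as sd


def make_obs(site="S1", box="B1", date="2005-06-15", sex="F", age="adult",
             mass=18.0, torpid=0, n_adults=1, n_juv=0, n_young=0):
    from datetime import date as _d
    d = _d.fromisoformat(date)
    return dm.Observation(site_id=site, box_id=box, date=d, year=d.year,
                          month=d.month, sex=sex, age_class=age, mass_g=mass,
                          torpid=torpid, n_adults_in_box=n_adults,
                          n_juveniles_in_box=n_juv, n_young_in_box=n_young)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete simulation: 8 sites x 4 years, ~1500 adult records."""
    return sd.SimulationConfig(n_sites=8, year_start=2004, year_end=2007,
                               boxes_per_site=40, occupancy_prob=0.15, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_clean_frame(small_dataset):
    records = dm.frame_to_observations(small_dataset["observations"])
    kept, _ = dm.clean_for_site_analysis(records, min_dormice_per_site=15)
    return dm.observations_to_frame(kept)
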