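import pandas as pd
import pytest

from pollinet import default_config, simulate_dataset
from pollinet.survey_data import (Dataset, EVENT_COLUMNS, PLANT_COLUMNS,
                                  SESSION_COLUMNS, SITE_COLUMNS,
                                  TAXONOMY_COLUMNS)


def make_dataset(sites=None, sessions=None, events=None, plants=None,
                 taxonomy=None) -> Dataset:
    """Build a small in-memory dataset from row tuples (see column lists)."""
    sites = sites if sites is not None else [
        ("s1", "Park One", "prestigious", 50.0, 6.0, 1000.0, 100.0, 0.0),
        ("s2", "Park Two", "rural_reference", 50.1, 6.1, 2000.0, 50.0,
         300.0),
    ]
    sessions = sessions if sessions is not None else [
        ("r1", "s1", "public_bed", "pb1", "2016-06-01", "10:00", 30.0,
         "21", "calm", "clear"),
        ("r2", "s2", "study_bed", "sb1", "2016-06-02", "11:00", 30.0,
         "22", "calm", "clear"),
    ]
    events = events if events is not None else [
        ("r1", "Plant A", "Apis mellifera", "blossom_visit", 3),
        ("r1", "Plant B", "Bombus terrestris", "blossom_visit", 2),
        ("r2", "Plant A", "hoverfly spp.", "reconnaissance", 1),
    ]
    plants = plants if plants is not None else [
        ("Plant A", "Asteraceae", "generalist"),
        ("Plant B", "Lamiaceae", "hymenoptera"),
    ]
    taxonomy = taxonomy if taxonomy is not None else [
        ("Apis mellifera", "Apis mellifera", "honeybee"),
        ("Bombus terrestris", "Bombus terrestris", "bumblebee"),
        ("hoverfly spp.", "hoverfly spp.", "hoverfly"),
    ]
    ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if len(ev):
        ev["count"] = ev["count"].astype(int)
    return Dataset(
        sites=pd.DataFrame(sites, columns=SITE_COLUMNS),
        sessions=pd.DataFrame(sessions, columns=SESSION_COLUMNS),
        events=ev,
        plants=pd.DataFrame(plants, columns=PLANT_COLUMNS),
        taxonomy=pd.DataFrame(taxonomy, columns=TAXONOMY_COLUMNS),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated survey under the default study conditions."""
    return simulate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=1)
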