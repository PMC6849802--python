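import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctiscape.synthetic import SimulationConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A dataset small enough for end-to-end stages in seconds."""
    return SimulationConfig(
        seed=7,
        n_species=24,
        n_sites=25,
        year_start=1995,
        year_end=2006,
        cell_size=200.0,
        site_spacing=6000.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def toy_sti():
    """Eight species with STIs 1..8 -> two per quartile assemblage."""
    return pd.DataFrame(
        {"species_id": [f"s{i}" for i in range(1, 9)], "sti": np.arange(1.0, 9.0)}
    )


def make_abundance(rows):
    """rows: (site, year, species, abundance, available)."""
    df = pd.DataFrame(
        rows, columns=["site_id", "year", "species_id", "abundance", "index_available"]
    )
    return df
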