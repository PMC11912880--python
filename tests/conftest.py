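import numpy as np
import pandas as pd
import pytest

from karstspat.synthetic import HotspotCenter, SyntheticScenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scenario():
    """One planted hotspot, patchy karst, dirty records enabled."""
    return SyntheticScenario(
        n_species=40,
        hotspot_centers=(HotspotCenter(121.0, 11.0),),
        karst_fraction=0.3,
        seed=7,
    )


def random_records(rng, n=100, n_species=10, bbox=(120.0, 10.0, 124.0, 14.0)):
    """Uniform random occurrence table for oracle comparisons."""
    west, south, east, north = bbox
    return pd.DataFrame(
        {
            "species": [f"sp{int(i)}" for i in rng.integers(0, n_species, n)],
            "decimalLongitude": rng.uniform(west, east, n),
            "decimalLatitude": rng.uniform(south, north, n),
            "source": rng.choice(
                ["field", "herbarium", "database", "literature"], n
            ),
        }
    )
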