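import pandas as pd
import pytest

from rarebiome.data_model import OTUTable, SampleMetadata
from rarebiome.synthetic import MetacommunityDesign, simulate_metacommunity


@pytest.fixture
def tiny_table() -> OTUTable:
    """4 samples x 6 OTUs, handcrafted counts with known structure."""
    data = pd.DataFrame(
        [
            [10, 5, 0, 1, 0, 4],
            [8, 7, 1, 0, 0, 4],
            [0, 0, 9, 6, 3, 2],
            [1, 0, 8, 7, 2, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"o{i}" for i in range(1, 7)],
    )
    return OTUTable(data)


@pytest.fixture
def tiny_meta(tiny_table) -> SampleMetadata:
    df = pd.DataFrame(
        {
            "habitat": ["mudflat", "mudflat", "mangrove", "mangrove"],
            "season": ["spring", "summer", "spring", "summer"],
            "latitude": [24.42, 24.42, 24.45, 24.45],
            "longitude": [117.88, 117.88, 117.91, 117.91],
            "pH": [7.1, 7.3, 6.8, 6.9],
            "TC": [12.0, 14.0, 22.0, 20.0],
            "salinity": [18.0, 19.0, 26.0, 25.0],
        },
        index=tiny_table.sample_ids,
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_community():
    """A 16-sample 4x4 metacommunity reused across read-only tests."""
    design = MetacommunityDesign(n_otus=400, depth=3000, seed=11)
    return simulate_metacommunity(design)
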