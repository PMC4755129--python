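import pandas as pd
import pytest

from biodisagg.regions import load_scheme, packaged_scheme
from biodisagg.synth import WorldSpec, generate_world


@pytest.fixture(scope="session")
def geo():
    return packaged_scheme("GEO")


@pytest.fixture(scope="session")
def ipbes():
    return packaged_scheme("IPBES")


@pytest.fixture(scope="session")
def world():
    """Default synthetic world with full truth record."""
    return generate_world(WorldSpec(seed=7))


@pytest.fixture
def toy_scheme():
    """Two regions, three countries, one special unit."""
    rows = pd.DataFrame(
        {
            "country_name": ["Alpha", "Beta", "Gamma", "High seas"],
            "iso3": ["AAA", "BBB", "CCC", ""],
            "region": ["North", "North", "South", "ABNJ"],
            "subregion": ["North-1", "North-2", "South-1", ""],
        }
    )
    return load_scheme(rows, name="toy")
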