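import pathlib

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def published_table() -> pd.DataFrame:
    """Printed chart cells (5 biometries x GA 16-38 x 7 centiles)."""
    return pd.read_csv(DATA / "published_velocity_centiles.csv")


@pytest.fixture(scope="session")
def standards():
    from fetalvelocity import published_standards

    return published_standards()
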