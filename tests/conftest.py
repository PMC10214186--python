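import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_species_csv(tmp_path):
    path = tmp_path / "species.csv"
    path.write_text(
        "species,country,year,index,se\n"
        "sp1,FR,2007,100,5\n"
        "sp1,FR,2008,90,4\n"
        "sp1,FR,2009,80,4\n")
    return path


@pytest.fixture
def small_pressure_panel():
    rows = []
    for c in ("FR", "DE"):
        for i, y in enumerate(range(2007, 2017)):
            rows.append({"country": c, "year": y, "pressure": "farm_input",
                         "value": 30.0 + 0.5 * i})
            rows.append({"country": c, "year": y, "pressure": "temperature",
                         "value": 9.0 + 0.1 * i})
    return pd.DataFrame(rows)
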