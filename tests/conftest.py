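import numpy as np
import pandas as pd
import pytest

from cigtaxsim import PanelDGPParams, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """22-country 1999-2015 panel at the default study conditions."""
    return generate_panel(PanelDGPParams(seed=1))


@pytest.fixture(scope="session")
def noise_free_panel():
    return generate_panel(PanelDGPParams(seed=3, error_sd=0.0))


@pytest.fixture()
def tiny_panel():
    """Hand-built 3-country, 5-year panel with exact values."""
    rng = np.random.default_rng(42)
    rows = []
    for i, c in enumerate(["A", "B", "C"]):
        for t, year in enumerate(range(2000, 2005)):
            rows.append({
                "country": c, "year": year,
                "consumption": 10 + 2 * i + rng.uniform(0, 3),
                "price": 1.0 + 0.3 * i + 0.1 * t + rng.uniform(0, 0.2),
                "gni": 1000 * (i + 1) * (1.03 ** t),
                "fctc": int(year >= 2002 + i),
                "cpi": 100 * (1.04 ** t),
            })
    return pd.DataFrame(rows)
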