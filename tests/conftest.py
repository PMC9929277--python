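import numpy as np
import pandas as pd
import pytest

from solarbag.labeling import TemperatureSeries
from solarbag.synthetic_data import generate_scenario


def make_series(temps, cadence=15, start="2018-07-26", **kw) -> TemperatureSeries:
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq=f"{cadence}min")
    return TemperatureSeries(timestamps=idx, temperatures=temps, **kw)


@pytest.fixture(scope="session")
def scenarios():
    """Lazily generated default campaigns, keyed by seed (shared across tests)."""
    cache = {}

    def get(seed: int):
        if seed not in cache:
            cache[seed] = generate_scenario(seed=seed)
        return cache[seed]

    return get


@pytest.fixture()
def toy_separable():
    """A linearly separable 2-feature table with the label column."""
    rng = np.random.default_rng(7)
    n = 60
    x1 = np.concatenate([rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)])
    x2 = rng.normal(0, 1, n)
    y = (x1 > 0).astype(int)
    return pd.DataFrame({"x1": x1, "x2": x2, "class_label": y})
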