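import numpy as np
import pandas as pd
import pytest

from dyadisc.isc import TimeSeriesPanel
from dyadisc.synthetic import NeuralSimConfig, simulate_neural_panel


@pytest.fixture(scope="session")
def tiny_panel() -> TimeSeriesPanel:
    """4 subjects x 2 videos x 3 regions, one subject missing video v02."""
    rng = np.random.default_rng(42)
    panel = TimeSeriesPanel()
    regions = ["rA", "rB", "rC"]
    for subject in ["s1", "s2", "s3", "s4"]:
        for video, n_t in (("v01", 60), ("v02", 40)):
            if subject == "s4" and video == "v02":
                continue  # partial data
            panel.add_cell(
                subject,
                video,
                {r: rng.standard_normal(n_t) for r in regions},
            )
    return panel


@pytest.fixture(scope="session")
def small_attrs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": ["s1", "s2", "s3", "s4"],
            "age": [18, 19, 22, 20],
            "gender": ["F", "M", "F", "F"],
            "country": ["USA", "USA", "Korea", "usa"],
        }
    )


@pytest.fixture(scope="session")
def small_ratings() -> pd.DataFrame:
    rows = []
    values = {"s1": 1, "s2": 2, "s3": 5, "s4": 3}
    for subject, rating in values.items():
        rows.append((subject, "v01", rating))
        if subject != "s4":
            rows.append((subject, "v02", min(rating + 1, 5)))
    return pd.DataFrame(rows, columns=["subject", "video", "rating"])


@pytest.fixture(scope="session")
def signal_panel_bundle():
    """Default-geometry panel with planted HH > LL effect in 3 signal regions."""
    config = NeuralSimConfig(seed=7)
    panel, ratings, attrs = simulate_neural_panel(config)
    return config, panel, ratings, attrs
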