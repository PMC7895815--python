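import numpy as np
import pandas as pd
import pytest

from itsynth import AnalysisWindow, RatePanel, SimConfig, generate_panel


@pytest.fixture
def window() -> AnalysisWindow:
    return AnalysisWindow(1990, 1999, 2013)


@pytest.fixture
def null_panel() -> RatePanel:
    """16-unit panel, 1990-2013, no intervention effect."""
    return generate_panel(SimConfig(seed=11, end_year=2013))


@pytest.fixture
def tiny_panel() -> RatePanel:
    """Deterministic panel where the treated unit is exactly
    0.6*A + 0.4*B and donors C, D are far away; no noise."""
    years = np.arange(1990, 2014)
    a = 40.0 + 0.5 * (years - 1990) + 1.5 * np.sin(np.arange(years.size))
    b = 30.0 - 0.3 * (years - 1990) + 1.0 * np.cos(np.arange(years.size))
    c = 80.0 + 0.1 * (years - 1990)
    d = 15.0 + 0.8 * (years - 1990)
    t = 0.6 * a + 0.4 * b
    rows = []
    for name, series in [("T", t), ("A", a), ("B", b), ("C", c), ("D", d)]:
        for y, r in zip(years, series):
            rows.append({"country": name, "year": int(y),
                         "age_group": "U18", "rate": float(r)})
    return RatePanel(pd.DataFrame(rows))


def make_panel_df(records):
    """Helper: long-format DataFrame from (country, year, rate) triples."""
    return pd.DataFrame([
        {"country": c, "year": y, "age_group": "U18", "rate": r}
        for c, y, r in records])
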