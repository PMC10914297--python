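import numpy as np
import pandas as pd
import pytest

from healthalloc import Panel, SCHEMA, SyntheticPanelParams, generate_panel


def make_frame(rows):
    """Build a schema frame from (region, year, pop, area, b, ht, lp, rn, cons, adm)."""
    return pd.DataFrame(rows, columns=SCHEMA)


@pytest.fixture
def tiny_panel():
    """Two regions × two years, hand-sized numbers."""
    return Panel(make_frame([
        ("A", 2017, 1000.0, 10.0, 10, 8, 4, 3, 5000, 120),
        ("A", 2018, 1010.0, 10.0, 11, 9, 4, 3, 5200, 130),
        ("B", 2017, 2000.0, 40.0, 30, 20, 9, 7, 9000, 300),
        ("B", 2018, 2020.0, 40.0, 31, 21, 9, 8, 9300, 310),
    ]))


@pytest.fixture
def proportional_panel():
    """Regions that are exact scalar multiples of one another: every
    per-base rate equal, every DMU on one CRS ray."""
    rows = []
    for year in (2017, 2018):
        for name, c in (("A", 1.0), ("B", 2.5), ("C", 7.0)):
            rows.append((name, year, 1000 * c, 10 * c, 10 * c, 8 * c,
                         4 * c, 3 * c, 5000 * c, 120 * c))
    return Panel(make_frame(rows))


@pytest.fixture(scope="session")
def paper_shaped_panel():
    """21 regions × 5 years with the study's default Gini targets."""
    return generate_panel(SyntheticPanelParams(seed=20170101 % (2**31)))


def pairwise_gini(values, bases):
    """Independent Gini oracle: base-share-weighted mean absolute
    difference of per-base rates, G = Σ_ij w_i w_j |r_i − r_j| / (2µ)."""
    v = np.asarray(values, float)
    b = np.asarray(bases, float)
    r = v / b
    w = b / b.sum()
    mu = float(w @ r)
    return float(np.sum(np.abs(r[:, None] - r[None, :]) * np.outer(w, w)) / (2 * mu))
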