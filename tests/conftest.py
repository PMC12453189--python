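import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cjspersist.records import COLUMNS


def make_records(rows):
    """Build a canonical record table from compact tuples.

    Each row: (record_id, species, date, lon, lat, unc, observer, source, state);
    trailing fields may be omitted.
    """
    full = []
    for r in rows:
        r = list(r) + [np.nan] * (9 - len(r))
        full.append(dict(zip(COLUMNS, r)))
    df = pd.DataFrame(full, columns=COLUMNS)
    df["event_date"] = df["event_date"].map(lambda d: d if isinstance(d, dt.date) else dt.date.fromisoformat(d))
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)
    df["coord_uncertainty_m"] = pd.to_numeric(df["coord_uncertainty_m"])
    return df


@pytest.fixture(scope="session")
def tiny_bundle():
    from cjspersist.simulate import fixture_bundle

    return fixture_bundle("tiny")


@pytest.fixture(scope="session")
def full_scale_bundle():
    from cjspersist.simulate import fixture_bundle

    return fixture_bundle("full-scale")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
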