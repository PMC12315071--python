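import numpy as np
import pandas as pd
import pytest

from hetstab import counteracting_params, generate_design, simulate_covers


@pytest.fixture(scope="session")
def study_design():
    """The study layout: 5 transects x 7 stations x 2 paired tiles."""
    return generate_design(5, 7, (0.1, 0.9), seed=1)


@pytest.fixture(scope="session")
def small_design():
    return generate_design(2, 3, (0.2, 0.8), seed=7)


@pytest.fixture(scope="session")
def study_covers(study_design):
    params = counteracting_params(seed=11)
    return simulate_covers(study_design, params), params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lmm_fixture():
    """Deterministic tile table with real transect and station effects.

    The reference statistics frozen in the tests were computed with R
    lme4/lmerTest 1.1-37/3.1-3 on exactly this table (REML, Satterthwaite).
    """
    gen = np.random.default_rng(0)
    rows = [
        (f"T{t}", f"T{t}S{s}", h, gen.uniform(0, 1))
        for t in range(5)
        for s in range(7)
        for h in (0, 1)
    ]
    df = pd.DataFrame(rows, columns=["transect_id", "station_id", "het", "emersion"])
    df["y_boundary"] = 0.5 * df.het + gen.normal(size=len(df))
    gen2 = np.random.default_rng(42)
    tr = {t: gen2.normal(0, 0.7) for t in df.transect_id.unique()}
    st = {s: gen2.normal(0, 0.5) for s in df.station_id.unique()}
    df["y_nested"] = (
        0.5 * df.het
        + df.transect_id.map(tr)
        + df.station_id.map(st)
        + gen2.normal(0, 1, len(df))
    )
    return df
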