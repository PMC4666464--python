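import numpy as np
import pandas as pd
import pytest

import gillnetkit as g


@pytest.fixture(scope="session")
def grayling():
    return g.DEFAULT_GRAYLING


@pytest.fixture(scope="session")
def small_survey():
    """A small deterministic synthetic survey shared across tests."""
    design = g.SurveyDesign(sites=("S1", "S2", "S3"), years=(2009, 2011, 2012, 2013))
    community = g.CommunityTrendConfig(
        species=(g.SpeciesTrend(name="grayling"),)
    )
    catch, sets, panels = g.simulate_catch_survey(design, community, seed=11)
    return catch, sets, panels


@pytest.fixture(scope="session")
def debris_transects():
    return pd.DataFrame(
        {
            "transect_id": [f"T{i}" for i in range(1, 6)],
            "site": [f"S{i}" for i in range(1, 6)],
            "year": 2013,
            "length_km": [2.0, 4.5, 1.0, 8.5, 3.0],
        }
    )


def set_cpue_frame(catch: pd.DataFrame, sets: pd.DataFrame) -> pd.DataFrame:
    """Per-set count CPUE including zero-catch sets."""
    n = catch.groupby("set_id").size().rename("n").reset_index()
    out = sets.merge(n, on="set_id", how="left").fillna({"n": 0})
    out["cpue"] = out["n"] / out["nights"]
    return out
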