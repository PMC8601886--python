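import io

import numpy as np
import pandas as pd
import pytest

from neighborgrowth import (
    PriorSpec,
    StudyRegion,
    SyntheticTruth,
    add_buffer_flag,
    basal_area,
    create_focal_vs_comp,
)


def census_frame(rows):
    """Build a canonical census DataFrame from (stem_id, sp, gx, gy, dbh, date,
    codes, alive) tuples."""
    df = pd.DataFrame(
        rows, columns=["stem_id", "sp", "gx", "gy", "dbh", "date", "codes", "alive"]
    )
    df["tree_id"] = df["stem_id"]
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture
def census_pair():
    """Two tiny censuses exactly 5 Julian years apart (1826.25 -> use 1826 days
    would not be exact; dates chosen so (date2-date1).days/365.25 == 6.0)."""
    d1, d2 = "2008-01-01", "2014-01-01"
    c1 = census_frame(
        [
            ("s1", "A", 10.0, 10.0, 10.0, d1, "", True),
            ("s2", "B", 12.0, 10.0, 20.0, d1, "", True),
            ("s3", "A", 50.0, 50.0, 15.0, d1, "", True),   # dies
            ("s4", "B", 60.0, 60.0, 12.0, d1, "", True),   # resprouts
            ("s5", "A", 70.0, 70.0, np.nan, d1, "", True),  # unmeasured
        ]
    )
    c2 = census_frame(
        [
            ("s1", "A", 10.0, 10.0, 13.0, d2, "", True),
            ("s2", "B", 12.0, 10.0, 23.0, d2, "M", True),
            ("s3", "A", 50.0, 50.0, np.nan, d2, "", False),
            ("s4", "B", 60.0, 60.0, 5.0, d2, "R", True),
            ("s5", "A", 70.0, 70.0, 11.0, d2, "", True),
        ]
    )
    return c1, c2


def annotated_growth(n=120, extent=80.0, seed=0, dist=7.5):
    """Random annotated growth table (buffer flag, fold, group, basal area)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "stem_id": [f"s{i}" for i in range(n)],
            "sp": rng.choice(["A", "B", "C"], size=n),
            "gx": rng.uniform(0, extent, n),
            "gy": rng.uniform(0, extent, n),
            "dbh1": rng.lognormal(2.3, 0.5, n),
            "growth": rng.normal(0.2, 0.1, n),
        }
    )
    df["group"] = pd.Categorical(df["sp"], categories=["A", "B", "C"])
    df["basal_area"] = basal_area(df["dbh1"].to_numpy())
    region = StudyRegion.rectangle(0, 0, extent, extent)
    df["buffer"] = add_buffer_flag(df, region, dist)
    df["fold_id"] = 1
    return df


@pytest.fixture
def growth_table():
    return annotated_growth()


@pytest.fixture
def focal_table(growth_table):
    return create_focal_vs_comp(growth_table, comp_dist=7.5)


@pytest.fixture
def small_truth():
    """Desk-size synthetic scene: ~300 stems, 3 species."""
    return SyntheticTruth(extent=(90.0, 90.0), intensity=0.04, seed=7)


@pytest.fixture
def weak_prior():
    return PriorSpec.default


def read_csv_text(text, **kw):
    return io.StringIO(text)
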