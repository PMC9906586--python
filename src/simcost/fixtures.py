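"""Published result tables embedded as machine-readable fixtures.

Five summary tables transcribed verbatim from the study this package
operationalizes — annual-averaged SIM and suicide counts, crude rates and
cost components (millions of 2019 dollars) for 1999/2000 and 2018/2019,
and per-capita costs with percent changes — for all 50 states, the
District of Columbia and the national row.  These anchor the regression
tests and the reporting layer's fixture replays.

Absolute dollar totals in the tables rest on unit-cost inputs that are not
public, so the fixtures are the only route to those magnitudes; ratios,
shares and percent changes are recomputable from them.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_paper_fixture",
    "jurisdictions",
    "NATIONAL_ROW",
    "back_solved_population",
    "bea_region_map",
]

NATIONAL_ROW = "UNITED STATES"

_FILES = {
    "T1": "table1_sim_1999_2000.csv",
    "T2": "table2_sim_2018_2019.csv",
    "T3": "table3_suicide_1999_2000.csv",
    "T4": "table4_suicide_2018_2019.csv",
    "T5": "table5_per_capita.csv",
}

#: (measure, period) -> mortality/cost table id
TABLE_FOR = {
    ("SIM", "1999/2000"): "T1",
    ("SIM", "2018/2019"): "T2",
    ("suicide", "1999/2000"): "T3",
    ("suicide", "2018/2019"): "T4",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("simcost.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_paper_fixture(table_id: str) -> pd.DataFrame:
    """One of the five printed tables, indexed by jurisdiction.

    T1–T4 columns: count, rate_per_100k, medical, work_loss, qol_loss,
    total (costs in millions of 2019 dollars, as printed).  T5 columns:
    per-capita dollars for both measures and periods plus the printed
    integer percent changes.
    """
    if table_id not in _FILES:
        raise KeyError(f"unknown table id {table_id!r}; expected one of {sorted(_FILES)}")
    return _read(_FILES[table_id]).set_index("jurisdiction")


def jurisdictions() -> list[str]:
    """The 51 jurisdictions (50 states + District of Columbia)."""
    t5 = load_paper_fixture("T5")
    return [j for j in t5.index if j != NATIONAL_ROW]


def back_solved_population(period: str) -> pd.Series:
    """Population denominators implied by printed SIM count and rate.

    population = count / rate × 100,000 from the SIM table of the period.
    Accurate only to the printed rate precision (±0.05 per 100,000).
    """
    tid = TABLE_FOR[("SIM", period)]
    t = load_paper_fixture(tid)
    return t["count"] / t["rate_per_100k"] * 1e5


def bea_region_map() -> dict[str, str]:
    """Jurisdiction → US Bureau of Economic Analysis region (8 regions)."""
    df = _read("bea_regions.csv")
    return dict(zip(df["jurisdiction"], df["region"]))
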