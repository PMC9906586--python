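"""The self-injury mortality (SIM) composite measure.

SIM broadens suicide into a composite of self-injurious deaths: all
registered suicides at any age (ICD-10 underlying cause U03, X60–X84,
Y87.0), plus 80% of drug-intoxication deaths medicolegally classified as
accidents (X40–X45) and 90% of those of undetermined intent (Y10–Y15),
the drug components restricted to decedents aged 15 and older.  The
fractions discount the minority of overdose deaths not attributable to
repetitive self-harm; the age cutoff reflects the rarity of purposive
self-harm among children.

Fractions are applied to expected (real-valued) counts, never by sampling
individual deaths, so the measure is deterministic.  Each two-year period
is annual-averaged to stabilize small-area values.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import (
    CauseClass,
    DeathStratum,
    Manner,
    Sex,
    WeightedCount,
    ICD10_RE,
    age_band_lower,
    period_label,
)

__all__ = [
    "SimWeights",
    "classify_cause",
    "sim_weight",
    "annual_average",
    "compute_weighted_counts",
    "crude_rate",
]

#: ICD-10 codes counted as suicide regardless of the certified manner.
#: X60–X84 are intentional self-harm; U03 terrorism-related self-harm;
#: Y87.0 sequelae of intentional self-harm (rare but honored if present).
_SUICIDE_EXACT = {"U03", "Y87.0"}


@dataclass(frozen=True)
class SimWeights:
    """Manner-specific fractions and the drug-component age cutoff."""

    suicide_weight: float = 1.0
    accident_drug_weight: float = 0.80
    undetermined_drug_weight: float = 0.90
    min_age_drug_component: int = 15

    def __post_init__(self) -> None:
        for name in ("suicide_weight", "accident_drug_weight", "undetermined_drug_weight"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w}")
        if self.min_age_drug_component < 0:
            raise ValueError("negative age cutoff")


def classify_cause(cause_code: str, manner: Manner | str) -> CauseClass:
    """Classify one (underlying cause, manner) pair for the composite.

    Suicide codes dominate the stated manner field; the drug-poisoning
    ranges carry their intent in the code itself (X4x accidental, Y1x
    undetermined), so X40–X45 only count when certified an accident.
    """
    manner = Manner(manner)
    code = cause_code.strip().upper()
    if not ICD10_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {cause_code!r}")
    letter, num = code[0], int(code[1:3])
    if code in _SUICIDE_EXACT or (letter == "X" and 60 <= num <= 84):
        return CauseClass.SUICIDE
    if letter == "X" and 40 <= num <= 45 and manner == Manner.ACCIDENT:
        return CauseClass.UNINTENTIONAL_DRUG
    if letter == "Y" and 10 <= num <= 15:
        return CauseClass.UNDETERMINED_DRUG
    return CauseClass.OTHER


def sim_weight(cause_class: CauseClass, age_group: str, weights: SimWeights) -> float:
    """Fraction of deaths in a stratum counted toward SIM.

    Suicides count at any age (including unknown age); the drug components
    apply only where the age band's lower bound clears the cutoff, so
    unknown-age records contribute nothing to them.
    """
    if cause_class == CauseClass.SUICIDE:
        return weights.suicide_weight
    if cause_class == CauseClass.OTHER:
        return 0.0
    lo = age_band_lower(age_group)
    if lo is None:
        # unknown-age records count only when the component is unrestricted
        if weights.min_age_drug_component > 0:
            return 0.0
    elif lo < weights.min_age_drug_component:
        return 0.0
    if cause_class == CauseClass.UNINTENTIONAL_DRUG:
        return weights.accident_drug_weight
    return weights.undetermined_drug_weight


def annual_average(count_year1: float, count_year2: float) -> float:
    """Two-year annual average (arithmetic mean), fractional preserved."""
    if count_year1 < 0 or count_year2 < 0:
        raise ValueError("counts must be non-negative")
    return (count_year1 + count_year2) / 2.0


def crude_rate(weighted_count: float, population: float) -> float:
    """Crude death rate per 100,000 population."""
    if population <= 0:
        raise ValueError("population must be positive")
    return weighted_count / population * 1e5


def _strata_frame(strata: list[DeathStratum]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [s.state for s in strata],
            "year": [s.year for s in strata],
            "cause_code": [s.cause_code for s in strata],
            "manner": [Manner(s.manner).value for s in strata],
            "age_group": [s.age_group for s in strata],
            "sex": [Sex(s.sex).value for s in strata],
            "deaths": [s.deaths for s in strata],
        }
    )


def weighted_counts_frame(
    df: pd.DataFrame, weights: SimWeights, period: tuple[int, int]
) -> pd.DataFrame:
    """Vectorized core of :func:`compute_weighted_counts`.

    Takes a deaths DataFrame (columns state, year, cause_code, manner,
    age_group, sex, deaths) and returns one row per
    (state, cause_class, age_group, sex) with the annual-averaged weighted
    count over the period.  Zero-weight rows are dropped.
    """
    y1, y2 = period
    years = set(df["year"].unique())
    for y in (y1, y2):
        if y not in years:
            raise ValueError(f"strata do not cover year {y} of period {period_label(period)}")
    df = df[df["year"].isin((y1, y2))]

    key = df["cause_code"].str.upper() + "|" + df["manner"].astype(str)
    classes = {
        k: classify_cause(*k.split("|", 1))  # type: ignore[arg-type]
        for k in key.unique()
    }
    df = df.assign(cause_class=key.map(classes))

    wkey = df["cause_class"].astype(str) + "|" + df["age_group"]
    wmap = {
        k: sim_weight(CauseClass(k.split("|")[0]), k.split("|")[1], weights)
        for k in wkey.unique()
    }
    df = df.assign(weight=wkey.map(wmap))
    df = df[df["weight"] > 0]

    grouped = (
        df.assign(weighted=df["deaths"] * df["weight"])
        .groupby(["state", "cause_class", "age_group", "sex", "year"], observed=True)["weighted"]
        .sum()
        .unstack("year", fill_value=0.0)
    )
    for y in (y1, y2):
        if y not in grouped.columns:
            grouped[y] = 0.0
    out = ((grouped[y1] + grouped[y2]) / 2.0).rename("weighted_deaths").reset_index()
    return out[out["weighted_deaths"] > 0].reset_index(drop=True)


def compute_weighted_counts(
    strata: list[DeathStratum], weights: SimWeights, period: tuple[int, int]
) -> list[WeightedCount]:
    """Annual-averaged weighted SIM counts per (state, class, age, sex).

    Weighting before or after averaging is equivalent (the weights are
    linear); this implementation weights each year then averages.
    """
    label = period_label(period)
    frame = weighted_counts_frame(_strata_frame(strata), weights, period)
    return [
        WeightedCount(
            state=row.state,
            period=label,
            cause_class=CauseClass(row.cause_class),
            age_group=row.age_group,
            sex=Sex(row.sex),
            weighted_deaths=float(row.weighted_deaths),
        )
        for row in frame.itertuples()
    ]
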