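"""Core domain types for state-level mortality cost accounting.

The pipeline's atomic input is an aggregated mortality cell
(:class:`DeathStratum`): a death count for one combination of jurisdiction,
calendar year, ICD-10 underlying-cause code, medicolegal manner of death,
5-year age band and sex — the shape of a CDC WONDER underlying-cause
extract.  Population denominators arrive as :class:`PopulationStratum`
records on the same grid (minus cause and manner).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum


class Manner(str, Enum):
    """Medicolegal manner-of-death category."""

    SUICIDE = "suicide"
    ACCIDENT = "accident"
    UNDETERMINED = "undetermined"
    OTHER = "other"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class CauseClass(str, Enum):
    """Classification of a (cause code, manner) pair for the SIM composite."""

    SUICIDE = "suicide"
    UNINTENTIONAL_DRUG = "unintentional_drug_poisoning"
    UNDETERMINED_DRUG = "undetermined_drug_poisoning"
    OTHER = "other"


#: Standard WONDER 5-year age bands, youngest to oldest.
AGE_BANDS: tuple[str, ...] = (
    "<1", "1-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85+",
)

UNKNOWN_AGE = "unknown"

_VALID_AGE_GROUPS = frozenset(AGE_BANDS) | {UNKNOWN_AGE}

_AGE_ALIAS = {
    "< 1 year": "<1", "<1 year": "<1", "under 1": "<1", "under 1 year": "<1",
    "1-4 years": "1-4", "85+ years": "85+", "not stated": UNKNOWN_AGE,
    "unknown": UNKNOWN_AGE,
}

ICD10_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,2})?$")


def normalize_age_band(label: str) -> str:
    """Map a WONDER-style age-group label onto the canonical band tokens."""
    s = label.strip()
    low = s.lower()
    if low in _AGE_ALIAS:
        return _AGE_ALIAS[low]
    s = re.sub(r"\s*years?$", "", s, flags=re.I).strip()
    if s in _VALID_AGE_GROUPS:
        return s
    raise ValueError(f"unrecognized age group label: {label!r}")


def age_band_lower(band: str) -> int | None:
    """Lower bound in years of a canonical age band; None for unknown age."""
    if band == UNKNOWN_AGE:
        return None
    if band == "<1":
        return 0
    if band.endswith("+"):
        return int(band[:-1])
    return int(band.split("-")[0])


def age_band_containing(age: int) -> str:
    """Canonical 5-year band containing an exact age in years."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    for band in reversed(AGE_BANDS):
        lo = age_band_lower(band)
        if lo is not None and age >= lo:
            return band
    raise AssertionError("unreachable")


def age_band_midpoint(band: str) -> int:
    """Representative single age used for per-death cost lookups.

    Midpoint of the band ('<1' → 0, '1-4' → 2, open-ended '85+' → 87).
    """
    lo = age_band_lower(band)
    if lo is None:
        raise ValueError("unknown age band has no representative age")
    if band == "<1":
        return 0
    if band.endswith("+"):
        return lo + 2
    hi = int(band.split("-")[1])
    return (lo + hi) // 2


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero.

    Display convention for percent changes, ratios and per-capita dollars;
    Python's built-in round() is banker's rounding and disagrees on halves.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _validate_jurisdiction_year(state: str, year: int) -> None:
    if not state or not state.strip():
        raise ValueError("empty jurisdiction name")
    if not 1900 <= year <= 2100:
        raise ValueError(f"implausible calendar year: {year}")


@dataclass(frozen=True)
class DeathStratum:
    """One aggregated mortality cell: count of deaths in a stratum."""

    state: str
    year: int
    cause_code: str
    manner: Manner
    age_group: str
    sex: Sex
    deaths: int

    def __post_init__(self) -> None:
        _validate_jurisdiction_year(self.state, self.year)
        if not ICD10_RE.match(self.cause_code):
            raise ValueError(f"malformed ICD-10 code: {self.cause_code!r}")
        if self.age_group not in _VALID_AGE_GROUPS:
            raise ValueError(f"unknown age group: {self.age_group!r}")
        if self.deaths < 0 or self.deaths != int(self.deaths):
            raise ValueError(f"deaths must be a non-negative integer: {self.deaths}")


@dataclass(frozen=True)
class PopulationStratum:
    """Population denominator for one (state, year, age band, sex) cell."""

    state: str
    year: int
    age_group: str
    sex: Sex
    population: int

    def __post_init__(self) -> None:
        _validate_jurisdiction_year(self.state, self.year)
        if self.age_group not in _VALID_AGE_GROUPS:
            raise ValueError(f"unknown age group: {self.age_group!r}")
        if self.population < 0:
            raise ValueError(f"negative population: {self.population}")


@dataclass(frozen=True)
class WeightedCount:
    """Annual-averaged, fraction-weighted deaths for one SIM stratum.

    ``weighted_deaths`` is real-valued: the composite applies its fractions
    to expected counts, never by sampling individual deaths, so the measure
    is deterministic.  Display rounding happens only in reports.
    """

    state: str
    period: str
    cause_class: CauseClass
    age_group: str
    sex: Sex
    weighted_deaths: float

    def __post_init__(self) -> None:
        if self.weighted_deaths < 0:
            raise ValueError("negative weighted deaths")


@dataclass(frozen=True)
class CostBreakdown:
    """Medical, work-loss and quality-of-life-loss dollars for a death set.

    ``total`` is always the exact full-precision sum of the components.
    """

    medical: float
    work_loss: float
    qol_loss: float

    def __post_init__(self) -> None:
        for name in ("medical", "work_loss", "qol_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} cost")

    @property
    def total(self) -> float:
        return self.medical + self.work_loss + self.qol_loss

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.medical + other.medical,
            self.work_loss + other.work_loss,
            self.qol_loss + other.qol_loss,
        )

    def scaled(self, k: float) -> "CostBreakdown":
        return CostBreakdown(self.medical * k, self.work_loss * k, self.qol_loss * k)


ZERO_COST = CostBreakdown(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class StatePeriodSummary:
    """One jurisdiction × two-year period row of a national summary table."""

    jurisdiction: str
    period: str
    measure: str                 # "SIM" or "suicide"
    weighted_count: float
    crude_rate: float            # per 100,000
    costs: CostBreakdown         # millions of base-year dollars
    per_capita: float            # dollars per person, full precision
    population: float


@dataclass(frozen=True)
class ChangeReport:
    """Per-capita cost change between two periods for one jurisdiction."""

    jurisdiction: str
    measure: str
    per_capita_start: float
    per_capita_end: float
    percent_change: int
    quintile: int | None = None   # 1 = largest increases … 5; None for national row
    region: str | None = None


def period_label(years: tuple[int, int]) -> str:
    y1, y2 = years
    if y2 != y1 + 1:
        raise ValueError(f"period must be two consecutive years, got {years}")
    return f"{y1}/{y2}"
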