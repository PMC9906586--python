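"""Per-death and aggregate cost model: medical, work loss, quality of life.

The accounting follows the standard fatal-injury costing framework used in
US public-health surveillance, extended with a value-per-statistical-life
(VSL) monetization of lost quality of life:

* **Medical** — a unit cost by place of death (scene/home, dead on arrival,
  emergency department, inpatient, nursing home, hospice) and injury
  mechanism, plus emergency transport for all deaths except those on
  scene/at home, plus coroner/medical-examiner cost for autopsied deaths.
* **Work loss** (human capital) — the present value of expected wages,
  fringe benefits and household work over the decedent's remaining life
  span, weighted by life-table probabilities of surviving each year of age
  to the next and discounted annually.
* **Quality-of-life loss** — VSL minus the population-average lifetime work
  loss gives the average lifetime quality-of-life value; dividing by life
  expectancy at birth gives a per-year value, which is streamed over the
  decedent's survival-weighted remaining years, discounted, and taken at a
  configurable fraction (default 80%) of the average person's loss.

Discounting convention: the year of death (k = 0) is undiscounted and the
k-th later year is discounted by (1+r)^-k.  All monetary inputs are
inflated to the base year with a price index before use.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .types import (
    UNKNOWN_AGE,
    CauseClass,
    CostBreakdown,
    Sex,
    age_band_containing,
    age_band_midpoint,
)

__all__ = [
    "PlaceOfDeath",
    "LifeTable",
    "EarningsSchedule",
    "MedicalCostTable",
    "ValuationConfig",
    "PriceIndex",
    "CostParameters",
    "ProfileMix",
    "DeathProfile",
    "discounted_work_loss",
    "average_lifetime_work_loss",
    "qol_per_year",
    "discounted_qol_loss",
    "medical_cost_per_death",
    "inflate_to_base_year",
    "cost_per_death",
    "aggregate_costs",
    "CostModel",
]


class PlaceOfDeath(str, Enum):
    SCENE_HOME = "scene_home"
    HOSPITAL_ARRIVAL = "hospital_arrival"
    EMERGENCY_DEPARTMENT = "emergency_department"
    HOSPITAL_INPATIENT = "hospital_inpatient"
    NURSING_HOME = "nursing_home"
    HOSPICE = "hospice"


class LifeTable:
    """Sex-specific annual survival probabilities and life expectancy.

    ``p[sex][a]`` is the probability of surviving from exact age ``a`` to
    ``a + 1``; the table closes at ``max_age`` (``p[max_age] = 0``).

    Life expectancy ``e(a)`` is the curtate expectation
    ``Σ_{k≥1} S(a → a+k)`` with ``S`` the cumulative survival product —
    the expected number of whole remaining years lived.  The annual cost
    streams weight the k-th remaining year by the probability of living
    through it, ``S(a → a+k+1)``, so the undiscounted unit stream from
    birth sums exactly to ``e(0)``; the curtate convention runs about half
    a year below the demographic complete expectation.
    """

    def __init__(self, survival: dict[Sex, np.ndarray]):
        self.p: dict[Sex, np.ndarray] = {}
        for sex in (Sex.FEMALE, Sex.MALE):
            if sex not in survival:
                raise ValueError(f"life table missing sex {sex.value}")
            arr = np.asarray(survival[sex], dtype=float)
            if arr.ndim != 1 or len(arr) < 2:
                raise ValueError("survival must be a 1-D array of length >= 2")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("survival probabilities must lie in [0, 1]")
            self.p[sex] = arr
        lengths = {len(a) for a in self.p.values()}
        if len(lengths) != 1:
            raise ValueError("survival arrays must share a common age range")
        self.max_age = lengths.pop() - 1
        if any(a[-1] != 0.0 for a in self.p.values()):
            raise ValueError(f"table must close: p(max_age={self.max_age}) must be 0")

    def cumulative_survival(self, sex: Sex, age: int) -> np.ndarray:
        """S(age → age+k) for k = 0 … max_age − age (S[0] = 1)."""
        if not 0 <= age <= self.max_age:
            raise ValueError(f"age {age} outside life table range 0–{self.max_age}")
        return np.concatenate(([1.0], np.cumprod(self.p[sex][age:])))[: self.max_age - age + 1]

    def year_weights(self, sex: Sex, age: int) -> np.ndarray:
        """Probability of living through each remaining year.

        Element k is S(age → age+k+1), the weight of the k-th remaining
        year's costs; the array is empty at the closing age.
        """
        return self.cumulative_survival(sex, age)[1:]

    def e(self, sex: Sex, age: int) -> float:
        """Curtate life expectancy: expected whole years remaining."""
        return float(self.year_weights(sex, age).sum())

    def e0(self, sex_weights: dict[Sex, float] | None = None) -> float:
        """Life expectancy at birth averaged over sexes."""
        w = sex_weights or {Sex.FEMALE: 0.5, Sex.MALE: 0.5}
        return sum(w[s] * self.e(s, 0) for s in (Sex.FEMALE, Sex.MALE))


class EarningsSchedule:
    """Average annual earnings (wages + fringe) and household-work value.

    Keyed by sex and 5-year age band; looked up for a single year of age by
    the band containing it.  Average earnings implicitly fold in employment
    probability and hours, so zeros (childhood, extreme old age) are valid.
    """

    def __init__(self, rows: dict[tuple[Sex, str], tuple[float, float]]):
        self.rows = {}
        for (sex, band), (earnings, household) in rows.items():
            if earnings < 0 or household < 0:
                raise ValueError(f"negative earnings entry for {sex}, {band}")
            self.rows[(Sex(sex), band)] = (float(earnings), float(household))

    def total_at_age(self, sex: Sex, age: int) -> float:
        band = age_band_containing(age)
        try:
            earnings, household = self.rows[(sex, band)]
        except KeyError:
            raise KeyError(f"earnings schedule has no cell for ({sex.value}, {band})") from None
        return earnings + household

    def totals_by_age(self, sex: Sex, max_age: int) -> np.ndarray:
        return np.array([self.total_at_age(sex, a) for a in range(max_age + 1)])


class MedicalCostTable:
    """Unit medical costs by place of death, mechanism and age band.

    ``'*'`` wildcards are accepted for mechanism and/or age band so sparse
    tables stay compact; lookup prefers the most specific cell.
    """

    def __init__(
        self,
        unit_costs: dict[tuple[str, str, str], float],
        transport_cost: float,
        autopsy_cost: float,
        autopsy_fraction: float,
    ):
        if transport_cost < 0 or autopsy_cost < 0:
            raise ValueError("negative transport or autopsy cost")
        if not 0.0 <= autopsy_fraction <= 1.0:
            raise ValueError("autopsy_fraction must be in [0, 1]")
        self.unit_costs = {}
        for (place, mech, band), cost in unit_costs.items():
            if cost < 0:
                raise ValueError(f"negative unit cost for {(place, mech, band)}")
            self.unit_costs[(PlaceOfDeath(place).value, mech, band)] = float(cost)
        self.transport_cost = float(transport_cost)
        self.autopsy_cost = float(autopsy_cost)
        self.autopsy_fraction = float(autopsy_fraction)

    def facility_cost(self, place: PlaceOfDeath, mechanism: str, age_group: str) -> float:
        p = PlaceOfDeath(place).value
        for key in (
            (p, mechanism, age_group),
            (p, mechanism, "*"),
            (p, "*", age_group),
            (p, "*", "*"),
        ):
            if key in self.unit_costs:
                return self.unit_costs[key]
        raise KeyError(
            f"medical cost table has no cell for place={p}, "
            f"mechanism={mechanism}, age_group={age_group}"
        )


@dataclass(frozen=True)
class ValuationConfig:
    """VSL, quality-of-life fraction, discount rate and base dollar year."""

    vsl: float = 10_700_000.0
    qol_fraction: float = 0.80
    discount_rate: float = 0.03
    base_year: int = 2019

    def __post_init__(self) -> None:
        if self.vsl <= 0:
            raise ValueError("vsl must be positive")
        if not 0.0 < self.qol_fraction <= 1.0:
            raise ValueError("qol_fraction must be in (0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")


class PriceIndex:
    """Annual price index used to express all costs in base-year dollars."""

    def __init__(self, values: dict[int, float]):
        if not values:
            raise ValueError("empty price index")
        for year, v in values.items():
            if v <= 0:
                raise ValueError(f"non-positive index value for {year}")
        self.values = {int(y): float(v) for y, v in values.items()}

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(f"price index has no entry for year {year}") from None


def inflate_to_base_year(
    amount: float, from_year: int, price_index: PriceIndex, base_year: int
) -> float:
    """Re-express ``amount`` (in ``from_year`` dollars) in base-year dollars."""
    return amount * price_index[base_year] / price_index[from_year]


@dataclass
class CostParameters:
    """Everything the cost engine needs, bundled."""

    life_table: LifeTable
    earnings: EarningsSchedule
    medical: MedicalCostTable
    valuation: ValuationConfig = field(default_factory=ValuationConfig)
    price_index: PriceIndex = field(default_factory=lambda: PriceIndex({2019: 1.0}))
    sex_weights: dict[Sex, float] = field(
        default_factory=lambda: {Sex.FEMALE: 0.5, Sex.MALE: 0.5}
    )
    dollar_year: int | None = None   # year the monetary inputs are expressed in

    def __post_init__(self) -> None:
        tot = sum(self.sex_weights.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"sex weights must sum to 1, got {tot}")

    @property
    def inflation_factor(self) -> float:
        """Multiplier taking input dollars to base-year dollars."""
        dy = self.dollar_year if self.dollar_year is not None else self.valuation.base_year
        return inflate_to_base_year(1.0, dy, self.price_index, self.valuation.base_year)


@dataclass(frozen=True)
class DeathProfile:
    """Decedent attributes that determine per-death cost."""

    sex: Sex
    age: int
    place: PlaceOfDeath
    mechanism: str


def _discount_factors(n: int, rate: float) -> np.ndarray:
    return (1.0 + rate) ** -np.arange(n, dtype=float)


def discounted_work_loss(
    sex: Sex,
    age_at_death: int,
    life_table: LifeTable,
    earnings: EarningsSchedule,
    discount_rate: float,
) -> float:
    """Present value of expected lifetime earnings lost to one death.

    Σ_k S(a → a+k+1) · E(a+k) · (1+r)^-k, where E combines wages, fringe
    benefits and household-work value: the k-th remaining year counts when
    it is lived through, year 0 undiscounted.
    """
    surv = life_table.year_weights(sex, age_at_death)
    earn = earnings.totals_by_age(sex, life_table.max_age)[age_at_death : age_at_death + len(surv)]
    return float(np.sum(surv * earn * _discount_factors(len(surv), discount_rate)))


def average_lifetime_work_loss(
    life_table: LifeTable,
    earnings: EarningsSchedule,
    discount_rate: float,
    sex_weights: dict[Sex, float] | None = None,
) -> float:
    """Sex-weighted discounted lifetime work loss evaluated at birth."""
    w = sex_weights or {Sex.FEMALE: 0.5, Sex.MALE: 0.5}
    return sum(
        w[s] * discounted_work_loss(s, 0, life_table, earnings, discount_rate)
        for s in (Sex.FEMALE, Sex.MALE)
    )


def qol_per_year(vsl: float, avg_lifetime_work_loss: float, life_expectancy_at_birth: float) -> float:
    """Dollar value of one year of quality of life for the average person.

    VSL minus average lifetime work loss is the average lifetime
    quality-of-life value; dividing by life expectancy annualizes it.
    """
    if life_expectancy_at_birth <= 0:
        raise ValueError("life expectancy must be positive")
    if vsl <= avg_lifetime_work_loss:
        raise ValueError(
            "VSL does not exceed average lifetime work loss; "
            "valuation configuration is inconsistent"
        )
    return (vsl - avg_lifetime_work_loss) / life_expectancy_at_birth


def discounted_qol_loss(
    sex: Sex,
    age_at_death: int,
    life_table: LifeTable,
    qol_year_value: float,
    qol_fraction: float,
    discount_rate: float,
) -> float:
    """Present value of the quality-of-life stream lost to one death.

    The per-year value is streamed over the decedent's survival-weighted
    remaining years exactly as work loss is, then scaled by the fraction
    applied to this decedent population (default 80% of the average
    person's loss).
    """
    if not 0.0 <= qol_fraction <= 1.0:
        raise ValueError("qol_fraction must be in [0, 1]")
    surv = life_table.year_weights(sex, age_at_death)
    stream = float(np.sum(surv * _discount_factors(len(surv), discount_rate)))
    return qol_fraction * qol_year_value * stream


def medical_cost_per_death(
    place: PlaceOfDeath,
    mechanism: str,
    age_group: str,
    autopsied: bool | float,
    table: MedicalCostTable,
) -> float:
    """Unit medical cost for one death.

    Transport is included for every death except those on scene/at home.
    ``autopsied`` may be a boolean (decedent-level flag) or a fraction in
    [0, 1] (aggregate expected-value mode).
    """
    place = PlaceOfDeath(place)
    cost = table.facility_cost(place, mechanism, age_group)
    if place != PlaceOfDeath.SCENE_HOME:
        cost += table.transport_cost
    frac = float(autopsied)
    if not 0.0 <= frac <= 1.0:
        raise ValueError("autopsied must be a boolean or a fraction in [0, 1]")
    return cost + frac * table.autopsy_cost


def cost_per_death(profile: DeathProfile, params: CostParameters) -> CostBreakdown:
    """Full cost breakdown for one death, in base-year dollars."""
    v = params.valuation
    infl = params.inflation_factor
    medical = (
        medical_cost_per_death(
            profile.place,
            profile.mechanism,
            age_band_containing(profile.age),
            params.medical.autopsy_fraction,
            params.medical,
        )
        * infl
    )
    work = (
        discounted_work_loss(
            profile.sex, profile.age, params.life_table, params.earnings, v.discount_rate
        )
        * infl
    )
    avg_wl = average_lifetime_work_loss(
        params.life_table, params.earnings, v.discount_rate, params.sex_weights
    ) * infl
    qpy = qol_per_year(v.vsl, avg_wl, params.life_table.e0(params.sex_weights))
    qol = discounted_qol_loss(
        profile.sex, profile.age, params.life_table, qpy, v.qol_fraction, v.discount_rate
    )
    return CostBreakdown(medical, work, qol)


class ProfileMix:
    """Distribution of (place of death, mechanism) by cause class.

    Aggregate inputs carry no decedent-level place/mechanism detail, so
    expected per-death medical cost is taken under this mix.
    """

    def __init__(
        self, mix: dict[CauseClass, list[tuple[PlaceOfDeath, str, float]]]
    ):
        self.mix: dict[CauseClass, list[tuple[PlaceOfDeath, str, float]]] = {}
        for cls, entries in mix.items():
            total = sum(w for _, _, w in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"profile mix for {CauseClass(cls).value} sums to {total}, not 1"
                )
            if any(w < 0 for _, _, w in entries):
                raise ValueError("negative profile-mix weight")
            self.mix[CauseClass(cls)] = [
                (PlaceOfDeath(p), m, float(w)) for p, m, w in entries
            ]

    def __getitem__(self, cls: CauseClass) -> list[tuple[PlaceOfDeath, str, float]]:
        return self.mix[CauseClass(cls)]


class CostModel:
    """Precomputed per-death cost lookups for fast aggregate evaluation.

    Work-loss and quality-of-life streams depend only on (sex, age); the
    expected medical cost depends on (cause class, age band) through the
    profile mix.  All values are in base-year dollars.
    """

    def __init__(self, params: CostParameters, mix: ProfileMix):
        self.params = params
        self.mix = mix
        v = params.valuation
        lt = params.life_table
        infl = params.inflation_factor
        disc = _discount_factors(lt.max_age + 1, v.discount_rate)

        self._work: dict[Sex, np.ndarray] = {}
        self._qstream: dict[Sex, np.ndarray] = {}
        for sex in (Sex.FEMALE, Sex.MALE):
            earn = params.earnings.totals_by_age(sex, lt.max_age)
            work = np.empty(lt.max_age + 1)
            qs = np.empty(lt.max_age + 1)
            for a in range(lt.max_age + 1):
                surv = lt.year_weights(sex, a)
                work[a] = np.sum(surv * earn[a : a + len(surv)] * disc[: len(surv)])
                qs[a] = np.sum(surv * disc[: len(surv)])
            self._work[sex] = work * infl
            self._qstream[sex] = qs

        avg_wl = sum(
            params.sex_weights[s] * self._work[s][0] for s in (Sex.FEMALE, Sex.MALE)
        )
        self.qol_year_value = qol_per_year(v.vsl, avg_wl, lt.e0(params.sex_weights))

    def work_loss(self, sex: Sex, age: int) -> float:
        return float(self._work[sex][age])

    def qol_loss(self, sex: Sex, age: int) -> float:
        return (
            self.params.valuation.qol_fraction
            * self.qol_year_value
            * float(self._qstream[sex][age])
        )

    def expected_medical(self, cause_class: CauseClass, age_group: str) -> float:
        table = self.params.medical
        cost = 0.0
        for place, mech, w in self.mix[cause_class]:
            cost += w * medical_cost_per_death(
                place, mech, age_group, table.autopsy_fraction, table
            )
        return cost * self.params.inflation_factor

    def expected_cost(
        self, cause_class: CauseClass, age_group: str, sex: Sex
    ) -> CostBreakdown:
        """Expected per-death cost for one aggregate stratum."""
        if age_group == UNKNOWN_AGE:
            # rare unknown-age suicides: cost at a mid-adult representative age
            age_group = "40-44"
        age = age_band_midpoint(age_group)
        age = min(age, self.params.life_table.max_age)
        return CostBreakdown(
            self.expected_medical(cause_class, age_group),
            self.work_loss(sex, age),
            self.qol_loss(sex, age),
        )


def aggregate_costs(
    weighted_counts,
    death_profile_mix: ProfileMix,
    params: CostParameters,
) -> dict[str, CostBreakdown]:
    """Total cost breakdown by state for a set of weighted SIM counts.

    Each stratum contributes ``weighted_deaths ×`` the expected per-death
    cost under the profile mix; every component is therefore linear in the
    counts.
    """
    model = CostModel(params, death_profile_mix)
    out: dict[str, CostBreakdown] = {}
    for wc in weighted_counts:
        per_death = model.expected_cost(wc.cause_class, wc.age_group, wc.sex)
        add = per_death.scaled(wc.weighted_deaths)
        out[wc.state] = out.get(wc.state, CostBreakdown(0, 0, 0)) + add
    return out
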