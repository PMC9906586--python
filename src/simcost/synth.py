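"""Synthetic mortality aggregates and cost parameters with known truth.

Emulates the structure of a national underlying-cause-of-death extract —
two two-year periods, ICD-10 self-harm and drug-poisoning code sets plus
unrelated noise codes, 5-year age bands, both sexes, 50 states + DC — with
configurable cause-specific rates, so every pipeline stage is testable
without any download.

Counts are Poisson (the natural law for rare-event death registration;
a negative-binomial option adds overdispersion for robustness checks).
Because a Poisson count thinned over a categorical code mix is again a set
of independent Poissons, the generator draws each (stratum, code) cell
directly at mean ``rate × multipliers × population / 100,000 × code
share``.  :func:`expected_truth` computes the corresponding analytic
expectations — no sampling — for parameter-recovery tests.

The ``paper_like`` preset encodes the study conditions this package
targets: periods 1999/2000 and 2018/2019, suicide rates rising ≈1.4×
between periods and drug-poisoning rates ≈2.5×, populations implied by
the fixture tables' printed counts and rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import (
    CostModel,
    CostParameters,
    EarningsSchedule,
    LifeTable,
    MedicalCostTable,
    PlaceOfDeath,
    PriceIndex,
    ProfileMix,
    ValuationConfig,
)
from .sim import SimWeights, sim_weight, weighted_counts_frame
from .types import (
    AGE_BANDS,
    CauseClass,
    CostBreakdown,
    DeathStratum,
    Manner,
    PopulationStratum,
    Sex,
    period_label,
)

__all__ = [
    "ScenarioConfig",
    "paper_like_preset",
    "small_preset",
    "generate_death_strata",
    "population_strata",
    "generate_parameter_bundle",
    "default_profile_mix",
    "expected_truth",
    "GroundTruth",
    "run_replicate",
]

# ICD-10 codes drawn per cause class, with manner and within-class shares.
# The last 'other' entry is a drug code certified with a manner outside the
# composite's rule (X44 undetermined) to exercise the classifier.
CODE_MIX: dict[CauseClass, list[tuple[str, Manner, float]]] = {
    CauseClass.SUICIDE: [
        ("X74", Manner.SUICIDE, 0.45),
        ("X70", Manner.SUICIDE, 0.20),
        ("X64", Manner.SUICIDE, 0.15),
        ("X80", Manner.SUICIDE, 0.10),
        ("X84", Manner.SUICIDE, 0.05),
        ("Y87.0", Manner.SUICIDE, 0.05),
    ],
    CauseClass.UNINTENTIONAL_DRUG: [
        ("X42", Manner.ACCIDENT, 0.50),
        ("X44", Manner.ACCIDENT, 0.35),
        ("X41", Manner.ACCIDENT, 0.15),
    ],
    CauseClass.UNDETERMINED_DRUG: [
        ("Y12", Manner.UNDETERMINED, 0.55),
        ("Y14", Manner.UNDETERMINED, 0.45),
    ],
    CauseClass.OTHER: [
        ("V43", Manner.ACCIDENT, 0.50),
        ("W13", Manner.ACCIDENT, 0.30),
        ("X44", Manner.UNDETERMINED, 0.20),
    ],
}

# Baseline (first-period) death rates per 100,000 by age band, male.
# Female rates apply the sex ratio below.  Shapes: suicide rises through
# midlife and again in old age; drug poisoning peaks at ages 25-54; small
# under-15 drug rates exercise the composite's age cutoff.
_SUICIDE_PROFILE = {
    "10-14": 1.5, "15-19": 8.0, "20-24": 12.0, "25-29": 13.0, "30-34": 13.0,
    "35-39": 14.0, "40-44": 15.0, "45-49": 16.0, "50-54": 16.0, "55-59": 15.0,
    "60-64": 13.0, "65-69": 12.0, "70-74": 13.0, "75-79": 15.0, "80-84": 17.0,
    "85+": 19.0,
}
_ACC_DRUG_PROFILE = {
    "1-4": 0.2, "5-9": 0.1, "10-14": 0.3, "15-19": 3.0, "20-24": 6.0,
    "25-29": 8.0, "30-34": 9.0, "35-39": 10.0, "40-44": 11.0, "45-49": 11.0,
    "50-54": 10.0, "55-59": 8.0, "60-64": 5.0, "65-69": 2.0, "70-74": 1.0,
    "75-79": 0.5, "80-84": 0.3, "85+": 0.2,
}
_OTHER_PROFILE = {band: 5.0 for band in AGE_BANDS}

#: male share of each cause's deaths (suicide is heavily male).
_MALE_SHARE = {
    CauseClass.SUICIDE: 0.78,
    CauseClass.UNINTENTIONAL_DRUG: 0.65,
    CauseClass.UNDETERMINED_DRUG: 0.60,
    CauseClass.OTHER: 0.55,
}

# US-like age pyramid shares (normalized at use).
_AGE_SHARES = {
    "<1": 1.2, "1-4": 5.0, "5-9": 6.5, "10-14": 6.8, "15-19": 6.9,
    "20-24": 6.7, "25-29": 6.6, "30-34": 6.5, "35-39": 6.8, "40-44": 7.0,
    "45-49": 7.2, "50-54": 6.8, "55-59": 6.0, "60-64": 5.0, "65-69": 4.0,
    "70-74": 3.4, "75-79": 2.8, "80-84": 2.2, "85+": 1.6,
}


def _rates_from_profiles() -> dict[CauseClass, dict[str, dict[Sex, float]]]:
    """Expand per-class male-referenced profiles to explicit (band, sex) rates."""
    profiles = {
        CauseClass.SUICIDE: _SUICIDE_PROFILE,
        CauseClass.UNINTENTIONAL_DRUG: _ACC_DRUG_PROFILE,
        CauseClass.UNDETERMINED_DRUG: {b: 0.3 * r for b, r in _ACC_DRUG_PROFILE.items()},
        CauseClass.OTHER: _OTHER_PROFILE,
    }
    out: dict[CauseClass, dict[str, dict[Sex, float]]] = {}
    for cls, profile in profiles.items():
        ms = _MALE_SHARE[cls]
        out[cls] = {
            band: {Sex.MALE: 2 * ms * rate, Sex.FEMALE: 2 * (1 - ms) * rate}
            for band, rate in profile.items()
        }
    return out


@dataclass
class ScenarioConfig:
    """Everything a synthetic scenario needs; the seed fixes all randomness."""

    jurisdictions: list[str]
    periods: list[tuple[int, int]]
    #: per-100,000 annual rates by cause class, age band and sex (first period)
    rates: dict[CauseClass, dict[str, dict[Sex, float]]] = field(
        default_factory=_rates_from_profiles
    )
    #: rate multiplier per period, by cause class (index-aligned with periods)
    period_multipliers: dict[CauseClass, tuple[float, ...]] = field(
        default_factory=lambda: {
            CauseClass.SUICIDE: (1.0, 1.4),
            CauseClass.UNINTENTIONAL_DRUG: (1.0, 2.5),
            CauseClass.UNDETERMINED_DRUG: (1.0, 2.5),
            CauseClass.OTHER: (1.0, 1.0),
        }
    )
    state_multipliers: dict[str, float] = field(default_factory=dict)
    #: total state population per period (distributed over bands/sexes below)
    state_populations: dict[str, tuple[float, ...]] = field(default_factory=dict)
    age_shares: dict[str, float] = field(default_factory=lambda: dict(_AGE_SHARES))
    seed: int = 0
    #: negative-binomial dispersion (None = pure Poisson)
    overdispersion: float | None = None
    max_age: int = 100

    def validate(self) -> None:
        if not self.jurisdictions:
            raise ValueError("no jurisdictions")
        if not self.periods:
            raise ValueError("no periods")
        for cls, bands in self.rates.items():
            for band, by_sex in bands.items():
                if band not in AGE_BANDS:
                    raise ValueError(f"unknown age band {band!r} in rates")
                for rate in by_sex.values():
                    if rate < 0:
                        raise ValueError(f"negative rate for {cls}, {band}")
        for cls, mults in self.period_multipliers.items():
            if len(mults) < len(self.periods):
                raise ValueError(f"period multipliers for {cls} do not cover all periods")
        for state in self.jurisdictions:
            pops = self.state_populations.get(state)
            if pops is None or len(pops) < len(self.periods):
                raise ValueError(f"missing population for {state!r}")
            if any(p <= 0 for p in pops):
                raise ValueError(f"non-positive population for {state!r}")

    def period_index(self, period: tuple[int, int]) -> int:
        try:
            return self.periods.index(tuple(period))
        except ValueError:
            raise ValueError(f"period {period} not in scenario") from None


def paper_like_preset(seed: int = 1) -> ScenarioConfig:
    """Scenario shaped like the national study conditions.

    All 51 jurisdictions; periods 1999/2000 and 2018/2019; populations
    back-solved from the fixture tables' printed counts and rates; drug
    rates rising 2.5× between periods against 1.4× for suicide, which
    shifts the composite toward the drug components just as the observed
    data did.
    """
    from .fixtures import back_solved_population, jurisdictions

    p0 = back_solved_population("1999/2000")
    p1 = back_solved_population("2018/2019")
    states = jurisdictions()
    return ScenarioConfig(
        jurisdictions=states,
        periods=[(1999, 2000), (2018, 2019)],
        state_populations={s: (float(p0[s]), float(p1[s])) for s in states},
        seed=seed,
    )


def small_preset(seed: int = 0) -> ScenarioConfig:
    """Three-jurisdiction scenario for fast unit tests."""
    pops = {"Alpha": (1.2e6, 1.3e6), "Beta": (4.0e6, 4.4e6), "Gamma": (0.6e6, 0.7e6)}
    return ScenarioConfig(
        jurisdictions=list(pops),
        periods=[(1999, 2000), (2018, 2019)],
        state_populations={k: v for k, v in pops.items()},
        state_multipliers={"Alpha": 1.3, "Gamma": 0.8},
        seed=seed,
    )


def _population_frame(config: ScenarioConfig, period_idx: int) -> pd.DataFrame:
    """Integer population per (state, age band, sex) for one period."""
    shares = pd.Series(config.age_shares, dtype=float)
    shares = shares / shares.sum()
    rows = []
    for state in config.jurisdictions:
        total = config.state_populations[state][period_idx]
        for band, share in shares.items():
            for sex in (Sex.FEMALE, Sex.MALE):
                rows.append(
                    {
                        "state": state,
                        "age_group": band,
                        "sex": sex.value,
                        "population": int(round(total * share / 2.0)),
                    }
                )
    return pd.DataFrame(rows)


def population_strata(config: ScenarioConfig, period: tuple[int, int]) -> list[PopulationStratum]:
    """Population records for both years of a period (held constant within it)."""
    config.validate()
    idx = config.period_index(period)
    frame = _population_frame(config, idx)
    out = []
    for year in period:
        for r in frame.itertuples():
            out.append(
                PopulationStratum(
                    state=r.state, year=year, age_group=r.age_group,
                    sex=Sex(r.sex), population=r.population,
                )
            )
    return out


def _mean_frame(config: ScenarioConfig, period_idx: int) -> pd.DataFrame:
    """Expected annual deaths per (state, band, sex, class, code) cell."""
    pop = _population_frame(config, period_idx)
    rows = []
    for cls, bands in config.rates.items():
        mult = config.period_multipliers[cls][period_idx]
        for band, by_sex in bands.items():
            for sex, rate in by_sex.items():
                if rate <= 0:
                    continue
                rows.append(
                    {
                        "cause_class": cls.value,
                        "age_group": band,
                        "sex": Sex(sex).value,
                        "rate": rate * mult,
                    }
                )
    rates = pd.DataFrame(rows, columns=["cause_class", "age_group", "sex", "rate"])
    grid = pop.merge(rates, on=["age_group", "sex"])
    grid["state_mult"] = grid["state"].map(
        lambda s: config.state_multipliers.get(s, 1.0)
    )
    grid["mean"] = grid["rate"] * grid["state_mult"] * grid["population"] / 1e5

    codes = pd.DataFrame(
        [
            {"cause_class": cls.value, "cause_code": code, "manner": manner.value, "share": w}
            for cls, entries in CODE_MIX.items()
            for code, manner, w in entries
        ]
    )
    grid = grid.merge(codes, on="cause_class")
    grid["mean"] = grid["mean"] * grid["share"]
    return grid[
        ["state", "age_group", "sex", "cause_class", "cause_code", "manner", "mean"]
    ].reset_index(drop=True)


def _draw_counts(means: np.ndarray, config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    if config.overdispersion is None:
        return rng.poisson(means)
    k = config.overdispersion
    if k <= 0:
        raise ValueError("overdispersion must be positive")
    lam = rng.gamma(shape=k, scale=means / k)
    return rng.poisson(lam)


def simulate_period_frame(
    config: ScenarioConfig,
    period: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sampled deaths DataFrame for both years of one period."""
    config.validate()
    idx = config.period_index(period)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = _mean_frame(config, idx)
    frames = []
    for year in period:
        f = mean.copy()
        f["year"] = year
        f["deaths"] = _draw_counts(f["mean"].to_numpy(dtype=float), config, rng)
        frames.append(f[f["deaths"] > 0])
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["state", "year", "cause_code", "manner", "age_group", "sex", "deaths"]
    ]


def generate_death_strata(
    config: ScenarioConfig,
    period: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> list[DeathStratum]:
    """Sampled mortality strata for one period as validated records."""
    frame = simulate_period_frame(config, period, rng)
    return [
        DeathStratum(
            state=r.state, year=int(r.year), cause_code=r.cause_code,
            manner=Manner(r.manner), age_group=r.age_group, sex=Sex(r.sex),
            deaths=int(r.deaths),
        )
        for r in frame.itertuples()
    ]


# --- cost parameters -------------------------------------------------------

def _survival_curve(max_age: int, sex: Sex) -> np.ndarray:
    """Gompertz-like annual survival closing at max_age."""
    ages = np.arange(max_age + 1, dtype=float)
    scale = 1.0 if sex == Sex.MALE else 0.62
    q = 0.0005 + scale * 4.5e-5 * np.exp(0.093 * ages)
    q[0] += 0.006  # infant mortality bump
    p = np.clip(1.0 - q, 0.0, 1.0)
    p[-1] = 0.0
    return p


_EARNINGS_PROFILE = {
    "15-19": 5_000, "20-24": 25_000, "25-29": 42_000, "30-34": 50_000,
    "35-39": 56_000, "40-44": 60_000, "45-49": 62_000, "50-54": 61_000,
    "55-59": 55_000, "60-64": 40_000, "65-69": 18_000, "70-74": 8_000,
    "75-79": 3_000,
}

_HOUSEHOLD_PROFILE = {
    "15-19": 3_000, "20-24": 8_000, "25-29": 12_000, "30-34": 14_000,
    "35-39": 14_000, "40-44": 14_000, "45-49": 13_000, "50-54": 13_000,
    "55-59": 12_000, "60-64": 12_000, "65-69": 11_000, "70-74": 9_000,
    "75-79": 7_000, "80-84": 5_000, "85+": 3_000,
}

_UNIT_MEDICAL = {
    PlaceOfDeath.SCENE_HOME: 600.0,
    PlaceOfDeath.HOSPITAL_ARRIVAL: 3_500.0,
    PlaceOfDeath.EMERGENCY_DEPARTMENT: 6_000.0,
    PlaceOfDeath.HOSPITAL_INPATIENT: 40_000.0,
    PlaceOfDeath.NURSING_HOME: 15_000.0,
    PlaceOfDeath.HOSPICE: 10_000.0,
}


def generate_parameter_bundle(config: ScenarioConfig) -> CostParameters:
    """Internally consistent synthetic cost parameters.

    Synthetic stand-ins: the real facility unit-cost schedule behind the
    published totals is not public, so these values are plausible
    magnitudes for testing, not estimates.  Deterministic given the
    scenario (no sampling).
    """
    life_table = LifeTable(
        {sex: _survival_curve(config.max_age, sex) for sex in (Sex.FEMALE, Sex.MALE)}
    )
    rows = {}
    for band in AGE_BANDS:
        earn = _EARNINGS_PROFILE.get(band, 0.0)
        house = _HOUSEHOLD_PROFILE.get(band, 0.0)
        # female wage gap on earnings; household value equal across sexes
        rows[(Sex.MALE, band)] = (earn * 1.1, house)
        rows[(Sex.FEMALE, band)] = (earn * 0.9, house)
    earnings = EarningsSchedule(rows)
    medical = MedicalCostTable(
        {(place.value, "*", "*"): cost for place, cost in _UNIT_MEDICAL.items()},
        transport_cost=900.0,
        autopsy_cost=2_100.0,
        autopsy_fraction=0.92,
    )
    price_index = PriceIndex({y: 1.02 ** (y - 2019) for y in range(1995, 2022)})
    return CostParameters(
        life_table=life_table,
        earnings=earnings,
        medical=medical,
        valuation=ValuationConfig(),
        price_index=price_index,
        dollar_year=2019,
    )


def default_profile_mix() -> ProfileMix:
    """Place-of-death / mechanism mixes per cause class.

    Aggregated away in published mortality extracts; these categorical
    distributions are the scenario's ground truth for the medical
    component (most self-harm and overdose deaths occur on scene/at home).
    """
    P = PlaceOfDeath
    return ProfileMix(
        {
            CauseClass.SUICIDE: [
                (P.SCENE_HOME, "firearm", 0.45),
                (P.SCENE_HOME, "suffocation", 0.15),
                (P.SCENE_HOME, "poisoning", 0.10),
                (P.HOSPITAL_ARRIVAL, "firearm", 0.05),
                (P.EMERGENCY_DEPARTMENT, "poisoning", 0.10),
                (P.HOSPITAL_INPATIENT, "poisoning", 0.15),
            ],
            CauseClass.UNINTENTIONAL_DRUG: [
                (P.SCENE_HOME, "poisoning", 0.60),
                (P.EMERGENCY_DEPARTMENT, "poisoning", 0.20),
                (P.HOSPITAL_INPATIENT, "poisoning", 0.15),
                (P.HOSPITAL_ARRIVAL, "poisoning", 0.05),
            ],
            CauseClass.UNDETERMINED_DRUG: [
                (P.SCENE_HOME, "poisoning", 0.60),
                (P.EMERGENCY_DEPARTMENT, "poisoning", 0.20),
                (P.HOSPITAL_INPATIENT, "poisoning", 0.15),
                (P.HOSPITAL_ARRIVAL, "poisoning", 0.05),
            ],
            CauseClass.OTHER: [
                (P.SCENE_HOME, "other", 0.70),
                (P.HOSPITAL_INPATIENT, "other", 0.30),
            ],
        }
    )


# --- analytic ground truth -------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic expectations for a scenario: no sampling anywhere.

    ``frame`` has one row per (state, period, cause_class) with the
    expected weighted count and expected cost components in base-year
    dollars.
    """

    frame: pd.DataFrame

    def national(self, period: tuple[int, int]) -> dict[str, float]:
        lbl = period_label(period)
        sub = self.frame[self.frame["period"] == lbl]
        return {
            "count": float(sub["expected_count"].sum()),
            "medical": float(sub["medical"].sum()),
            "work_loss": float(sub["work_loss"].sum()),
            "qol_loss": float(sub["qol_loss"].sum()),
        }

    def state_counts(self, period: tuple[int, int]) -> pd.Series:
        lbl = period_label(period)
        sub = self.frame[self.frame["period"] == lbl]
        return sub.groupby("state")["expected_count"].sum()


def _cost_lookup(model: CostModel) -> pd.DataFrame:
    """Per-death expected cost components by (class, band, sex)."""
    rows = []
    for cls in CauseClass:
        if cls == CauseClass.OTHER:
            continue
        for band in AGE_BANDS:
            for sex in (Sex.FEMALE, Sex.MALE):
                c = model.expected_cost(cls, band, sex)
                rows.append(
                    {
                        "cause_class": cls.value, "age_group": band, "sex": sex.value,
                        "medical": c.medical, "work_loss": c.work_loss,
                        "qol_loss": c.qol_loss,
                    }
                )
    return pd.DataFrame(rows)


def expected_truth(
    config: ScenarioConfig,
    weights: SimWeights | None = None,
    params: CostParameters | None = None,
    mix: ProfileMix | None = None,
) -> GroundTruth:
    """Expected weighted counts and costs implied by the scenario."""
    config.validate()
    weights = weights or SimWeights()
    params = params or generate_parameter_bundle(config)
    mix = mix or default_profile_mix()
    model = CostModel(params, mix)
    lookup = _cost_lookup(model)

    frames = []
    for idx, period in enumerate(config.periods):
        mean = _mean_frame(config, idx)
        # collapse the code dimension back to class level
        cls = (
            mean.groupby(["state", "cause_class", "age_group", "sex"], observed=True)["mean"]
            .sum()
            .reset_index()
        )
        cls["weight"] = [
            sim_weight(CauseClass(r.cause_class), r.age_group, weights)
            for r in cls.itertuples()
        ]
        cls["expected_count"] = cls["mean"] * cls["weight"]
        cls = cls[cls["expected_count"] > 0]
        cls = cls.merge(lookup, on=["cause_class", "age_group", "sex"], how="left")
        for comp in ("medical", "work_loss", "qol_loss"):
            cls[comp] = cls[comp] * cls["expected_count"]
        agg = (
            cls.groupby(["state", "cause_class"], observed=True)[
                ["expected_count", "medical", "work_loss", "qol_loss"]
            ]
            .sum()
            .reset_index()
        )
        agg["period"] = period_label(period)
        frames.append(agg)
    return GroundTruth(pd.concat(frames, ignore_index=True))


def run_replicate(
    config: ScenarioConfig,
    period: tuple[int, int],
    rng: np.random.Generator,
    weights: SimWeights,
    model: CostModel,
    lookup: pd.DataFrame | None = None,
) -> dict[str, float]:
    """One sampled pipeline pass: national weighted count and cost totals.

    Fast path for Monte-Carlo studies; equivalent to generating records,
    running the composite measure and aggregating costs.
    """
    if lookup is None:
        lookup = _cost_lookup(model)
    deaths = simulate_period_frame(config, period, rng)
    wc = weighted_counts_frame(deaths, weights, period)
    wc = wc.merge(lookup, on=["cause_class", "age_group", "sex"], how="left")
    return {
        "count": float(wc["weighted_deaths"].sum()),
        "medical": float((wc["medical"] * wc["weighted_deaths"]).sum()),
        "work_loss": float((wc["work_loss"] * wc["weighted_deaths"]).sum()),
        "qol_loss": float((wc["qol_loss"] * wc["weighted_deaths"]).sum()),
    }
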