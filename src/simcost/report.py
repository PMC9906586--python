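"""Result surfaces: summaries, per-capita changes, ratios, ranks, quintiles.

Display conventions match every checkable printed cell of the source
tables: percent changes and component ratios round to the nearest integer
with halves away from zero; per-capita costs round to the nearest dollar;
cost components display in millions to one decimal.  National rows are
always computed from national totals, never by summing display-rounded
state rows.
"""
from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .costs import CostModel, CostParameters, ProfileMix
from .fixtures import NATIONAL_ROW, bea_region_map, load_paper_fixture
from .types import (
    ChangeReport,
    CostBreakdown,
    PopulationStratum,
    StatePeriodSummary,
    WeightedCount,
    round_half_away,
)

__all__ = [
    "per_capita",
    "percent_change",
    "component_ratio",
    "composition_shares",
    "rank_jurisdictions",
    "assign_quintiles",
    "quintile_thresholds",
    "region_of",
    "summarize_period",
    "build_change_report",
    "change_report_from_fixtures",
]

QUINTILE_SIZES = (11, 10, 10, 10, 10)


def per_capita(total_cost: float, population: float) -> float:
    """Dollars per person at full precision; display rounds to the dollar."""
    if population <= 0:
        raise ValueError("population must be positive")
    return total_cost / population


def percent_change(start: float, end: float) -> int:
    """Integer percent change, halves rounded away from zero."""
    if start == 0:
        raise ValueError("percent change undefined for zero start value")
    return round_half_away((end - start) / start * 100.0)


def component_ratio(component: float, medical: float) -> int:
    """Ratio of an indirect cost component to medical spending, as printed."""
    if medical <= 0:
        raise ValueError("medical spending must be positive")
    return round_half_away(component / medical)


def composition_shares(
    suicide_count: float,
    accident_drug_weighted: float,
    undetermined_drug_weighted: float,
) -> tuple[float, float, float]:
    """Fractional composition of the SIM composite by manner component."""
    parts = (suicide_count, accident_drug_weighted, undetermined_drug_weighted)
    if any(p < 0 for p in parts):
        raise ValueError("negative component")
    total = sum(parts)
    if total == 0:
        raise ValueError("empty composite: zero total")
    return tuple(p / total for p in parts)  # type: ignore[return-value]


def rank_jurisdictions(values: dict[str, float]) -> list[tuple[str, float]]:
    """Jurisdictions ordered by descending metric; ties break alphabetically."""
    if len(set(values)) != len(values):
        raise ValueError("duplicate jurisdiction")
    return sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_quintiles(values: dict[str, float]) -> dict[str, int]:
    """Quintile labels (1 = largest values … 5) for exactly 51 jurisdictions.

    Deterministic rule: sort descending and take quintile sizes
    (11, 10, 10, 10, 10) from the top; when a tie straddles a boundary all
    tied jurisdictions share the better quintile and the shortfall comes
    out of the bottom quintiles.
    """
    if len(values) != 51:
        raise ValueError(f"quintiles are defined over 51 jurisdictions, got {len(values)}")
    ordered = rank_jurisdictions(values)
    labels: dict[str, int] = {}
    i = 0
    for q, size in enumerate(QUINTILE_SIZES, start=1):
        if i >= len(ordered):
            break
        take = min(size, len(ordered) - i)
        j = i + take
        # extend through any tie with the last value taken
        while j < len(ordered) and ordered[j][1] == ordered[j - 1][1]:
            j += 1
        for name, _ in ordered[i:j]:
            labels[name] = q
        i = j
    for name, _ in ordered[i:]:
        labels[name] = 5
    return labels


def quintile_thresholds(values: dict[str, float]) -> list[float]:
    """Smallest value in each quintile, best to worst (one per nonempty quintile)."""
    labels = assign_quintiles(values)
    mins: dict[int, float] = {}
    for name, q in labels.items():
        mins[q] = min(mins.get(q, float("inf")), values[name])
    return [mins[q] for q in sorted(mins)]


def region_of(jurisdiction: str) -> str:
    """US Bureau of Economic Analysis region of a jurisdiction."""
    regions = bea_region_map()
    try:
        return regions[jurisdiction]
    except KeyError:
        raise KeyError(f"unknown jurisdiction {jurisdiction!r}") from None


def _population_by_state(
    populations: list[PopulationStratum], period: tuple[int, int]
) -> dict[str, float]:
    """Annual-averaged total population per state over the period."""
    y1, y2 = period
    by_year: dict[str, dict[int, float]] = defaultdict(lambda: {y1: 0.0, y2: 0.0})
    for p in populations:
        if p.year in (y1, y2):
            by_year[p.state][p.year] += p.population
    return {s: (d[y1] + d[y2]) / 2.0 for s, d in by_year.items()}


def summarize_period(
    weighted_counts: list[WeightedCount],
    populations: list[PopulationStratum],
    params: CostParameters,
    profile_mix: ProfileMix,
    measure: str,
    period: tuple[int, int],
) -> list[StatePeriodSummary]:
    """State rows plus the national row for one measure and period.

    Costs are reported in millions of base-year dollars; per-capita in
    dollars per person at full precision.
    """
    from .types import period_label

    label = period_label(period)
    model = CostModel(params, profile_mix)
    pop = _population_by_state(populations, period)

    counts: dict[str, float] = defaultdict(float)
    costs: dict[str, CostBreakdown] = defaultdict(lambda: CostBreakdown(0, 0, 0))
    for wc in weighted_counts:
        counts[wc.state] += wc.weighted_deaths
        costs[wc.state] = costs[wc.state] + model.expected_cost(
            wc.cause_class, wc.age_group, wc.sex
        ).scaled(wc.weighted_deaths)

    rows: list[StatePeriodSummary] = []
    for state in sorted(counts):
        if state not in pop:
            raise ValueError(f"no population denominator for {state!r}")
        rows.append(_summary_row(state, label, measure, counts[state], costs[state], pop[state]))

    nat_count = sum(counts.values())
    nat_cost = CostBreakdown(
        sum(c.medical for c in costs.values()),
        sum(c.work_loss for c in costs.values()),
        sum(c.qol_loss for c in costs.values()),
    )
    nat_pop = sum(pop[s] for s in counts)
    rows.append(_summary_row(NATIONAL_ROW, label, measure, nat_count, nat_cost, nat_pop))
    return rows


def _summary_row(state, label, measure, count, cost, population) -> StatePeriodSummary:
    return StatePeriodSummary(
        jurisdiction=state,
        period=label,
        measure=measure,
        weighted_count=count,
        crude_rate=count / population * 1e5,
        costs=cost.scaled(1e-6),
        per_capita=per_capita(cost.total, population),
        population=population,
    )


def build_change_report(
    start: list[StatePeriodSummary] | dict[str, float],
    end: list[StatePeriodSummary] | dict[str, float],
    measure: str,
) -> list[ChangeReport]:
    """Per-jurisdiction per-capita percent change with quintile and region.

    Accepts either summary rows or plain jurisdiction → per-capita
    mappings.  Both periods must cover the same 51 jurisdictions; a
    national row, when present, is carried through without quintile or
    region.  Quintile 1 holds the largest increases.
    """
    def as_map(x):
        if isinstance(x, dict):
            return dict(x)
        return {s.jurisdiction: s.per_capita for s in x}

    pc0, pc1 = as_map(start), as_map(end)
    missing = set(pc0) ^ set(pc1)
    if missing:
        raise ValueError(f"jurisdictions present in only one period: {sorted(missing)}")

    states = [j for j in pc0 if j != NATIONAL_ROW]
    changes = {j: percent_change(pc0[j], pc1[j]) for j in pc0}
    quintiles = assign_quintiles({j: changes[j] for j in states})
    regions = bea_region_map()

    out = [
        ChangeReport(
            jurisdiction=j,
            measure=measure,
            per_capita_start=pc0[j],
            per_capita_end=pc1[j],
            percent_change=changes[j],
            quintile=quintiles.get(j),
            region=regions.get(j),
        )
        for j in sorted(states)
    ]
    if NATIONAL_ROW in pc0:
        out.append(
            ChangeReport(
                jurisdiction=NATIONAL_ROW,
                measure=measure,
                per_capita_start=pc0[NATIONAL_ROW],
                per_capita_end=pc1[NATIONAL_ROW],
                percent_change=changes[NATIONAL_ROW],
            )
        )
    return out


def change_report_from_fixtures(measure: str) -> list[ChangeReport]:
    """Change report recomputed from the embedded per-capita fixture table.

    Percent changes are recomputed from the printed (dollar-rounded)
    per-capita values; the printed change column itself remains available
    in the fixture for comparison.
    """
    t5 = load_paper_fixture("T5")
    key = "sim" if measure == "SIM" else "suicide"
    start = t5[f"{key}_pc_1999_2000"].astype(float).to_dict()
    end = t5[f"{key}_pc_2018_2019"].astype(float).to_dict()
    return build_change_report(start, end, measure)
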