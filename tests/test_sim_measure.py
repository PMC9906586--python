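"""The SIM composite: classification, weighting, averaging, rates."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simcost import (
    CauseClass,
    DeathStratum,
    Manner,
    Sex,
    SimWeights,
    annual_average,
    classify_cause,
    compute_weighted_counts,
    crude_rate,
    sim_weight,
)
from simcost.types import AGE_BANDS, UNKNOWN_AGE, age_band_lower


@pytest.mark.parametrize(
    "code,manner,expected",
    [
        ("X64", Manner.SUICIDE, CauseClass.SUICIDE),
        ("X60", Manner.SUICIDE, CauseClass.SUICIDE),
        ("X84", Manner.SUICIDE, CauseClass.SUICIDE),
        ("U03", Manner.OTHER, CauseClass.SUICIDE),
        ("Y87.0", Manner.OTHER, CauseClass.SUICIDE),
        # suicide code set dominates a discordant manner field
        ("X70", Manner.ACCIDENT, CauseClass.SUICIDE),
        ("X42", Manner.ACCIDENT, CauseClass.UNINTENTIONAL_DRUG),
        ("X40", Manner.ACCIDENT, CauseClass.UNINTENTIONAL_DRUG),
        ("X45", Manner.ACCIDENT, CauseClass.UNINTENTIONAL_DRUG),
        # accidental-poisoning codes without an accident manner fall out
        ("X44", Manner.UNDETERMINED, CauseClass.OTHER),
        ("Y12", Manner.UNDETERMINED, CauseClass.UNDETERMINED_DRUG),
        ("Y10", Manner.UNDETERMINED, CauseClass.UNDETERMINED_DRUG),
        ("Y15", Manner.UNDETERMINED, CauseClass.UNDETERMINED_DRUG),
        ("Y16", Manner.UNDETERMINED, CauseClass.OTHER),
        ("X39", Manner.ACCIDENT, CauseClass.OTHER),
        ("X46", Manner.ACCIDENT, CauseClass.OTHER),
        ("V43", Manner.ACCIDENT, CauseClass.OTHER),
        ("Y87.1", Manner.OTHER, CauseClass.OTHER),
    ],
)
def test_classify_cause(code, manner, expected):
    assert classify_cause(code, manner) == expected


@pytest.mark.parametrize("bad", ["", "X6", "6X4", "x", "X600.0", "Q"])
def test_classify_rejects_malformed_codes(bad):
    with pytest.raises(ValueError):
        classify_cause(bad, Manner.SUICIDE)


@pytest.mark.parametrize(
    "cause_class,age_group,expected",
    [
        (CauseClass.SUICIDE, "10-14", 1.0),       # any age, incl. below cutoff
        (CauseClass.SUICIDE, UNKNOWN_AGE, 1.0),
        (CauseClass.UNINTENTIONAL_DRUG, "45-49", 0.8),
        (CauseClass.UNINTENTIONAL_DRUG, "15-19", 0.8),   # cutoff band included
        (CauseClass.UNINTENTIONAL_DRUG, "10-14", 0.0),
        (CauseClass.UNINTENTIONAL_DRUG, UNKNOWN_AGE, 0.0),
        (CauseClass.UNDETERMINED_DRUG, "85+", 0.9),
        (CauseClass.UNDETERMINED_DRUG, "10-14", 0.0),
        (CauseClass.OTHER, "45-49", 0.0),
    ],
)
def test_sim_weight_defaults(cause_class, age_group, expected):
    assert sim_weight(cause_class, age_group, SimWeights()) == expected


def test_annual_average():
    assert annual_average(100, 100) == 100
    assert annual_average(0, 50) == 25
    assert annual_average(3, 4) == 3.5
    with pytest.raises(ValueError):
        annual_average(-1, 5)


def test_crude_rate():
    assert crude_rate(100, 1_000_000) == 10.0
    assert crude_rate(0, 12345) == 0.0
    with pytest.raises(ValueError):
        crude_rate(5, 0)


def test_crude_rate_reproduces_printed_state_rate():
    # population implied by the printed count and rate round-trips the rate
    pop = 1036 / 57.6 * 1e5
    assert crude_rate(1036, pop) == pytest.approx(57.6, abs=0.05)


def _stratum(code, manner, age, deaths, year, state="S", sex=Sex.MALE):
    return DeathStratum(
        state=state, year=year, cause_code=code, manner=manner,
        age_group=age, sex=sex, deaths=deaths,
    )


def test_weighted_counts_simple_cases():
    strata = [
        _stratum("X74", Manner.SUICIDE, "40-44", 10, 1999),
        _stratum("X74", Manner.SUICIDE, "40-44", 10, 2000),
        _stratum("X44", Manner.ACCIDENT, "25-29", 10, 1999),
        _stratum("X44", Manner.ACCIDENT, "25-29", 10, 2000),
    ]
    out = compute_weighted_counts(strata, SimWeights(), (1999, 2000))
    by_class = {wc.cause_class: wc.weighted_deaths for wc in out}
    assert by_class[CauseClass.SUICIDE] == 10.0
    assert by_class[CauseClass.UNINTENTIONAL_DRUG] == pytest.approx(8.0)


def test_weighted_counts_missing_year_is_named():
    strata = [_stratum("X74", Manner.SUICIDE, "40-44", 5, 1999)]
    with pytest.raises(ValueError, match="2000"):
        compute_weighted_counts(strata, SimWeights(), (1999, 2000))


def _brute_force(strata, weights, period):
    """Independent oracle: per-record classify/weight/average loop."""
    acc = {}
    for s in strata:
        if s.year not in period:
            continue
        w = sim_weight(classify_cause(s.cause_code, s.manner), s.age_group, weights)
        if w == 0:
            continue
        key = (s.state, classify_cause(s.cause_code, s.manner), s.age_group, s.sex)
        acc.setdefault(key, {period[0]: 0.0, period[1]: 0.0})
        acc[key][s.year] += s.deaths * w
    return {k: (v[period[0]] + v[period[1]]) / 2 for k, v in acc.items()}


CODES = [
    ("X74", Manner.SUICIDE), ("Y87.0", Manner.SUICIDE), ("X42", Manner.ACCIDENT),
    ("X44", Manner.ACCIDENT), ("X44", Manner.UNDETERMINED), ("Y12", Manner.UNDETERMINED),
    ("V43", Manner.ACCIDENT), ("U03", Manner.OTHER),
]

strata_lists = st.lists(
    st.builds(
        _stratum,
        st.sampled_from([c for c, _ in CODES]),
        st.sampled_from([m for _, m in CODES]),
        st.sampled_from(list(AGE_BANDS) + [UNKNOWN_AGE]),
        st.integers(min_value=0, max_value=50),
        st.sampled_from([1999, 2000]),
        st.sampled_from(["A", "B"]),
        st.sampled_from(list(Sex)),
    ),
    min_size=2,
    max_size=40,
).filter(lambda ss: {s.year for s in ss} == {1999, 2000})


@settings(deadline=None, max_examples=60)
@given(strata_lists)
def test_weighted_counts_match_brute_force(strata):
    weights = SimWeights()
    expected = _brute_force(strata, weights, (1999, 2000))
    out = compute_weighted_counts(strata, weights, (1999, 2000))
    got = {}
    for wc in out:
        key = (wc.state, wc.cause_class, wc.age_group, wc.sex)
        got[key] = got.get(key, 0.0) + wc.weighted_deaths
    expected = {k: v for k, v in expected.items() if v > 0}
    assert set(got) == set(expected)
    for k in expected:
        assert got[k] == pytest.approx(expected[k])


@settings(deadline=None, max_examples=40)
@given(strata_lists)
def test_no_op_weights_recover_raw_counts(strata):
    """All weights 1 and cutoff 0 reduce SIM to the raw code-set count."""
    weights = SimWeights(1.0, 1.0, 1.0, 0)
    out = compute_weighted_counts(strata, weights, (1999, 2000))
    total = sum(wc.weighted_deaths for wc in out)
    raw = sum(
        s.deaths
        for s in strata
        if classify_cause(s.cause_code, s.manner) != CauseClass.OTHER
    )
    assert total == pytest.approx(raw / 2)


@settings(deadline=None, max_examples=40)
@given(
    strata_lists,
    st.floats(min_value=0, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_weighted_count_monotone_and_bounded(strata, w_acc, w_und):
    """SIM total is monotone in each weight and never exceeds raw deaths."""
    lo = SimWeights(1.0, w_acc * 0.5, w_und * 0.5)
    hi = SimWeights(1.0, w_acc, w_und)
    t_lo = sum(w.weighted_deaths for w in compute_weighted_counts(strata, lo, (1999, 2000)))
    t_hi = sum(w.weighted_deaths for w in compute_weighted_counts(strata, hi, (1999, 2000)))
    raw = sum(s.deaths for s in strata) / 2
    assert t_lo <= t_hi + 1e-9
    assert t_hi <= raw + 1e-9


def test_weight_then_average_commutes_with_average_then_weight():
    strata = [
        _stratum("X42", Manner.ACCIDENT, "30-34", 7, 1999),
        _stratum("X42", Manner.ACCIDENT, "30-34", 12, 2000),
    ]
    weights = SimWeights()
    out = compute_weighted_counts(strata, weights, (1999, 2000))
    averaged_first = annual_average(7, 12) * 0.8
    assert out[0].weighted_deaths == pytest.approx(averaged_first)


def test_age_cutoff_uses_band_lower_bound():
    assert age_band_lower("15-19") == 15
    assert sim_weight(CauseClass.UNDETERMINED_DRUG, "15-19", SimWeights()) == 0.9
    # raising the cutoff past the band's lower bound excludes it
    assert sim_weight(
        CauseClass.UNDETERMINED_DRUG, "15-19", SimWeights(min_age_drug_component=16)
    ) == 0.0
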