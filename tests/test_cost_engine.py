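"""Cost engine: discounted streams, medical assembly, identities."""
import numpy as np
import pytest

from simcost import (
    AGE_BANDS,
    CauseClass,
    CostModel,
    CostParameters,
    DeathProfile,
    MedicalCostTable,
    PlaceOfDeath,
    PriceIndex,
    ProfileMix,
    Sex,
    ValuationConfig,
    aggregate_costs,
    average_lifetime_work_loss,
    cost_per_death,
    discounted_qol_loss,
    discounted_work_loss,
    inflate_to_base_year,
    medical_cost_per_death,
    qol_per_year,
)
from simcost.types import WeightedCount

from conftest import flat_earnings, make_life_table, zero_medical


def brute_work_loss(p, earn_by_age, age, r):
    """Element-by-element oracle: survive each year to earn that year."""
    total, alive = 0.0, 1.0
    for k in range(len(p) - age):
        alive *= p[age + k]
        total += alive * earn_by_age[age + k] / (1 + r) ** k
    return total


def brute_qol_stream(p, age, r):
    total, alive = 0.0, 1.0
    for k in range(len(p) - age):
        alive *= p[age + k]
        total += alive / (1 + r) ** k
    return total


class TestWorkLoss:
    def test_undiscounted_constant_stream(self):
        lt = make_life_table([1.0] * 10 + [0.0])
        earn = flat_earnings(50_000.0)
        assert discounted_work_loss(Sex.MALE, 0, lt, earn, 0.0) == pytest.approx(500_000.0)

    def test_immediate_death_is_zero(self):
        lt = make_life_table([0.0, 0.0])
        assert discounted_work_loss(Sex.MALE, 0, lt, flat_earnings(9e9), 0.0) == 0.0

    def test_age_beyond_table_raises(self):
        lt = make_life_table([1.0, 0.0])
        with pytest.raises(ValueError):
            discounted_work_loss(Sex.MALE, 5, lt, flat_earnings(1.0), 0.0)

    @pytest.mark.parametrize("age", [0, 2, 4])
    @pytest.mark.parametrize("r", [0.0, 0.03, 0.10])
    def test_matches_brute_force_on_random_toy_tables(self, age, r):
        rng = np.random.default_rng(2024 + age)
        for _ in range(20):
            n = 6
            p = np.append(rng.uniform(0.2, 1.0, n - 1), 0.0)
            lt = make_life_table(p)
            amount = rng.uniform(1e3, 8e4)
            earn = flat_earnings(amount)
            earn_by_age = [amount] * n
            got = discounted_work_loss(Sex.FEMALE, age, lt, earn, r)
            want = brute_work_loss(p, earn_by_age, age, r)
            assert got == pytest.approx(want, rel=1e-9)

    def test_monotone_nonincreasing_in_discount_rate(self, toy_params):
        lt, earn = toy_params.life_table, toy_params.earnings
        vals = [discounted_work_loss(Sex.MALE, 3, lt, earn, r) for r in (0.0, 0.01, 0.03, 0.1)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestAverageWorkLossAndQol:
    def test_identical_sexes_symmetry(self):
        lt = make_life_table([0.95] * 8 + [0.0])
        earn = flat_earnings(20_000.0)
        avg = average_lifetime_work_loss(lt, earn, 0.03)
        assert avg == pytest.approx(discounted_work_loss(Sex.MALE, 0, lt, earn, 0.03))

    def test_degenerate_sex_weights(self, toy_params):
        lt, earn = toy_params.life_table, toy_params.earnings
        male_only = average_lifetime_work_loss(lt, earn, 0.03, {Sex.FEMALE: 0.0, Sex.MALE: 1.0})
        assert male_only == pytest.approx(discounted_work_loss(Sex.MALE, 0, lt, earn, 0.03))

    def test_qol_per_year_arithmetic(self):
        assert qol_per_year(10_700_000, 0, 80.0) == pytest.approx(133_750.0)
        assert qol_per_year(100.0 + 78.0, 100.0, 78.0) == pytest.approx(1.0)
        assert qol_per_year(10_700_000, 1_200_000, 78.0) == pytest.approx(121_794.87, abs=0.01)
        with pytest.raises(ValueError):
            qol_per_year(1_000_000, 2_000_000, 78.0)

    def test_qol_loss_zero_fraction_and_flat_stream(self):
        lt = make_life_table([1.0] * 10 + [0.0])
        assert discounted_qol_loss(Sex.MALE, 0, lt, 1000.0, 0.0, 0.0) == 0.0
        v = 1234.5
        assert discounted_qol_loss(Sex.MALE, 0, lt, v, 0.8, 0.0) == pytest.approx(8 * v * 10 / 10)

    def test_qol_loss_matches_brute_force(self):
        rng = np.random.default_rng(99)
        p = np.append(rng.uniform(0.3, 1.0, 7), 0.0)
        lt = make_life_table(p)
        for r in (0.0, 0.03):
            got = discounted_qol_loss(Sex.FEMALE, 1, lt, 50_000.0, 0.8, r)
            want = 0.8 * 50_000.0 * brute_qol_stream(p, 1, r)
            assert got == pytest.approx(want, rel=1e-9)

    def test_qol_loss_linear_in_fraction(self, toy_params):
        lt = toy_params.life_table
        half = discounted_qol_loss(Sex.MALE, 2, lt, 1e5, 0.4, 0.03)
        full = discounted_qol_loss(Sex.MALE, 2, lt, 1e5, 0.8, 0.03)
        assert full == pytest.approx(2 * half, rel=1e-12)


class TestMedical:
    def table(self, scene=100.0, hosp=40_000.0, transport=900.0, autopsy=2000.0, frac=0.5):
        return MedicalCostTable(
            {
                ("scene_home", "*", "*"): scene,
                ("hospital_inpatient", "*", "*"): hosp,
            },
            transport_cost=transport,
            autopsy_cost=autopsy,
            autopsy_fraction=frac,
        )

    def test_zero_table_scene_death(self):
        t = self.table(scene=0.0, transport=0.0, autopsy=0.0)
        assert medical_cost_per_death(PlaceOfDeath.SCENE_HOME, "x", "40-44", False, t) == 0.0

    def test_scene_death_gets_no_transport(self):
        t = self.table(scene=100.0, autopsy=2000.0)
        got = medical_cost_per_death(PlaceOfDeath.SCENE_HOME, "x", "40-44", True, t)
        assert got == pytest.approx(100.0 + 2000.0)

    def test_facility_death_gets_transport(self):
        t = self.table()
        got = medical_cost_per_death(PlaceOfDeath.HOSPITAL_INPATIENT, "x", "40-44", False, t)
        assert got == pytest.approx(40_000.0 + 900.0)

    def test_expected_autopsy_fraction_mode(self):
        t = self.table(frac=0.5)
        got = medical_cost_per_death(PlaceOfDeath.SCENE_HOME, "x", "40-44", 0.25, t)
        assert got == pytest.approx(100.0 + 0.25 * 2000.0)

    def test_missing_cell_names_the_cell(self):
        t = MedicalCostTable({("hospice", "poisoning", "40-44"): 1.0}, 0, 0, 0)
        with pytest.raises(KeyError, match="hospice.*firearm"):
            t.facility_cost(PlaceOfDeath.HOSPICE, "firearm", "30-34")


def test_inflation():
    idx = PriceIndex({1999: 150.0, 2019: 300.0})
    assert inflate_to_base_year(100.0, 2019, idx, 2019) == 100.0
    assert inflate_to_base_year(100.0, 1999, idx, 2019) == pytest.approx(200.0)
    with pytest.raises(KeyError):
        inflate_to_base_year(1.0, 1980, idx, 2019)


class TestCostPerDeath:
    def test_all_zero_parameters_give_zero_breakdown(self):
        lt = make_life_table([1.0] * 5 + [0.0])
        params = CostParameters(
            life_table=lt,
            earnings=flat_earnings(0.0),
            medical=zero_medical(),
            valuation=ValuationConfig(vsl=1.0, qol_fraction=1e-12 + 0.5),
        )
        # zero earnings and a tiny VSL: medical and work are exactly zero
        b = cost_per_death(
            DeathProfile(Sex.MALE, 2, PlaceOfDeath.SCENE_HOME, "*"), params
        )
        assert b.medical == 0.0 and b.work_loss == 0.0

    def test_decomposition_identity_average_newborn(self, toy_params):
        """work + QoL = VSL for the average newborn at r=0, fraction 1."""
        params = CostParameters(
            life_table=toy_params.life_table,
            earnings=toy_params.earnings,
            medical=zero_medical(),
            valuation=ValuationConfig(qol_fraction=1.0, discount_rate=0.0),
        )
        model = CostModel(params, ProfileMix({c: [(PlaceOfDeath.SCENE_HOME, "*", 1.0)] for c in CauseClass}))
        total = sum(
            0.5 * (model.work_loss(s, 0) + model.qol_loss(s, 0)) for s in Sex
        )
        assert total == pytest.approx(params.valuation.vsl, rel=1e-12)

    def test_component_oracle_assembly(self, toy_params):
        """cost_per_death equals its independently computed components."""
        params = toy_params
        prof = DeathProfile(Sex.FEMALE, 7, PlaceOfDeath.SCENE_HOME, "*")
        b = cost_per_death(prof, params)
        v = params.valuation
        wl = discounted_work_loss(Sex.FEMALE, 7, params.life_table, params.earnings, v.discount_rate)
        avg = average_lifetime_work_loss(params.life_table, params.earnings, v.discount_rate)
        qpy = qol_per_year(v.vsl, avg, params.life_table.e0())
        ql = discounted_qol_loss(Sex.FEMALE, 7, params.life_table, qpy, v.qol_fraction, v.discount_rate)
        assert b.work_loss == pytest.approx(wl, rel=1e-12)
        assert b.qol_loss == pytest.approx(ql, rel=1e-12)
        assert b.total == pytest.approx(b.medical + b.work_loss + b.qol_loss, rel=1e-15)


class TestAggregate:
    def wc(self, state, n, cls=CauseClass.SUICIDE, band="40-44", sex=Sex.MALE):
        return WeightedCount(state, "1999/2000", cls, band, sex, n)

    def test_degenerate_mix_single_stratum(self, params, profile_mix):
        out = aggregate_costs([self.wc("A", 3.0)], profile_mix, params)
        model = CostModel(params, profile_mix)
        per = model.expected_cost(CauseClass.SUICIDE, "40-44", Sex.MALE)
        assert out["A"].total == pytest.approx(3.0 * per.total, rel=1e-12)

    def test_linearity_in_counts(self, params, profile_mix):
        single = aggregate_costs(
            [self.wc("A", 2.0), self.wc("A", 1.0, band="20-24")], profile_mix, params
        )
        double = aggregate_costs(
            [self.wc("A", 4.0), self.wc("A", 2.0, band="20-24")], profile_mix, params
        )
        for comp in ("medical", "work_loss", "qol_loss"):
            assert getattr(double["A"], comp) == pytest.approx(
                2 * getattr(single["A"], comp), rel=1e-12
            )

    def test_multi_strata_brute_force(self, params, profile_mix):
        rng = np.random.default_rng(5)
        classes = [CauseClass.SUICIDE, CauseClass.UNINTENTIONAL_DRUG]
        bands = ["20-24", "40-44", "85+"]
        sexes = list(Sex)
        strata = [
            self.wc(
                state=s, n=float(rng.integers(1, 30)),
                cls=classes[rng.integers(len(classes))],
                band=bands[rng.integers(len(bands))],
                sex=sexes[rng.integers(len(sexes))],
            )
            for s in ["A", "A", "B", "B", "B"]
        ]
        out = aggregate_costs(strata, profile_mix, params)
        model = CostModel(params, profile_mix)
        for state in ("A", "B"):
            want = 0.0
            for wc in strata:
                if wc.state == state:
                    want += wc.weighted_deaths * model.expected_cost(
                        wc.cause_class, wc.age_group, wc.sex
                    ).total
            assert out[state].total == pytest.approx(want, rel=1e-12)

    def test_unnormalized_mix_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            ProfileMix({CauseClass.SUICIDE: [(PlaceOfDeath.SCENE_HOME, "*", 0.7)]})
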