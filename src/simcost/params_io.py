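"""Cost-parameter bundle on disk: one YAML document plus delimited tables.

Layout of a bundle directory::

    bundle.yaml        scalars + file references (schema below)
    life_table.csv     sex, age, p          (one-year survival probability)
    earnings.csv       sex, age_group, earnings, household
    medical_costs.csv  place, mechanism, age_group, cost   ('*' wildcards ok)
    price_index.csv    year, value

The YAML schema is versioned and strict: unknown keys are rejected, so a
typo in a scalar name fails loudly instead of silently falling back to a
default.
"""
from __future__ import annotations

import pathlib

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .costs import (
    CostParameters,
    EarningsSchedule,
    LifeTable,
    MedicalCostTable,
    PriceIndex,
    ValuationConfig,
)
from .types import Sex

__all__ = ["load_parameter_bundle", "save_parameter_bundle", "BundleConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ValuationSection(_Strict):
    vsl: float = 10_700_000.0
    qol_fraction: float = 0.80
    discount_rate: float = 0.03
    base_year: int = 2019


class FilesSection(_Strict):
    life_table: str = "life_table.csv"
    earnings: str = "earnings.csv"
    medical_costs: str = "medical_costs.csv"
    price_index: str = "price_index.csv"


class BundleConfig(_Strict):
    """Schema of ``bundle.yaml``."""

    schema_version: int = Field(1, ge=1, le=1)
    valuation: ValuationSection = ValuationSection()
    sex_weights: dict[str, float] = {"female": 0.5, "male": 0.5}
    transport_cost: float = 0.0
    autopsy_cost: float = 0.0
    autopsy_fraction: float = 0.0
    dollar_year: int | None = None
    files: FilesSection = FilesSection()


def load_parameter_bundle(path: str | pathlib.Path) -> CostParameters:
    """Load a bundle directory into a validated :class:`CostParameters`."""
    path = pathlib.Path(path)
    cfg = BundleConfig.model_validate(
        yaml.safe_load((path / "bundle.yaml").read_text())
    )

    lt_df = pd.read_csv(path / cfg.files.life_table, float_precision="round_trip")
    survival = {}
    for sex in (Sex.FEMALE, Sex.MALE):
        sub = lt_df[lt_df["sex"] == sex.value].sort_values("age")
        if not (sub["age"].values == range(len(sub))).all():
            raise ValueError(f"life table ages for {sex.value} must run 0..max contiguously")
        survival[sex] = sub["p"].to_numpy()
    life_table = LifeTable(survival)

    earn_df = pd.read_csv(path / cfg.files.earnings, float_precision="round_trip")
    earnings = EarningsSchedule(
        {
            (Sex(r.sex), r.age_group): (r.earnings, r.household)
            for r in earn_df.itertuples()
        }
    )

    med_df = pd.read_csv(path / cfg.files.medical_costs, float_precision="round_trip")
    medical = MedicalCostTable(
        {(r.place, str(r.mechanism), str(r.age_group)): r.cost for r in med_df.itertuples()},
        transport_cost=cfg.transport_cost,
        autopsy_cost=cfg.autopsy_cost,
        autopsy_fraction=cfg.autopsy_fraction,
    )

    idx_df = pd.read_csv(path / cfg.files.price_index, float_precision="round_trip")
    price_index = PriceIndex(dict(zip(idx_df["year"], idx_df["value"])))

    return CostParameters(
        life_table=life_table,
        earnings=earnings,
        medical=medical,
        valuation=ValuationConfig(**cfg.valuation.model_dump()),
        price_index=price_index,
        sex_weights={Sex(k): v for k, v in cfg.sex_weights.items()},
        dollar_year=cfg.dollar_year,
    )


def save_parameter_bundle(params: CostParameters, path: str | pathlib.Path) -> None:
    """Write a :class:`CostParameters` out as a bundle directory."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = BundleConfig(
        valuation=ValuationSection(
            vsl=params.valuation.vsl,
            qol_fraction=params.valuation.qol_fraction,
            discount_rate=params.valuation.discount_rate,
            base_year=params.valuation.base_year,
        ),
        sex_weights={s.value: w for s, w in params.sex_weights.items()},
        transport_cost=params.medical.transport_cost,
        autopsy_cost=params.medical.autopsy_cost,
        autopsy_fraction=params.medical.autopsy_fraction,
        dollar_year=params.dollar_year,
    )
    (path / "bundle.yaml").write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))

    rows = []
    for sex, p in params.life_table.p.items():
        for age, pa in enumerate(p):
            rows.append({"sex": sex.value, "age": age, "p": pa})
    pd.DataFrame(rows).to_csv(path / cfg.files.life_table, index=False, float_format="%.17g")

    rows = [
        {"sex": sex.value, "age_group": band, "earnings": e, "household": h}
        for (sex, band), (e, h) in params.earnings.rows.items()
    ]
    pd.DataFrame(rows).to_csv(path / cfg.files.earnings, index=False, float_format="%.17g")

    rows = [
        {"place": p, "mechanism": m, "age_group": a, "cost": c}
        for (p, m, a), c in params.medical.unit_costs.items()
    ]
    pd.DataFrame(rows).to_csv(path / cfg.files.medical_costs, index=False, float_format="%.17g")

    pd.DataFrame(
        sorted(params.price_index.values.items()), columns=["year", "value"]
    ).to_csv(path / cfg.files.price_index, index=False, float_format="%.17g")
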