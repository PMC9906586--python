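"""Reading and writing WONDER-style tab-delimited mortality exports.

The dialect mirrors the CDC WONDER "Underlying Cause of Death" export:
tab-delimited with a header row, optionally quoted fields, an optional
leading ``Notes`` column, a sentinel token (default ``Suppressed``) for
cells below the publication threshold, ``Total`` rows, and free-text notes
trailing the data.  Underlying cause only — contributing-cause records are
out of scope.
"""
from __future__ import annotations

import csv
import io
import logging
import warnings
from typing import Iterable, Literal, TextIO

import pandas as pd

from .types import (
    DeathStratum,
    Manner,
    PopulationStratum,
    Sex,
    normalize_age_band,
)

logger = logging.getLogger(__name__)

__all__ = ["parse_wonder_export", "write_records", "write_summary_table"]

DEFAULT_SUPPRESSED = "Suppressed"

_DEATH_COLUMNS = ("State", "Year", "Cause Code", "Manner", "Age Group", "Sex", "Deaths")
_POP_COLUMNS = ("State", "Year", "Age Group", "Sex", "Population")

_SEX_ALIAS = {"female": Sex.FEMALE, "f": Sex.FEMALE, "male": Sex.MALE, "m": Sex.MALE}
_MANNER_ALIAS = {m.value: m for m in Manner} | {
    "unintentional": Manner.ACCIDENT,
    "accident (unintentional)": Manner.ACCIDENT,
}


class WonderFormatError(ValueError):
    """Malformed export: missing column or unparseable structure."""


class WonderValidationError(ValueError):
    """A data row failed validation; message carries the row number."""


def _header_map(header: list[str], required: tuple[str, ...]) -> dict[str, int]:
    idx = {name.strip().lower(): i for i, name in enumerate(header)}
    out = {}
    for col in required:
        key = col.lower()
        if key not in idx:
            raise WonderFormatError(f"export header is missing column {col!r}")
        out[col] = idx[key]
    return out


def parse_wonder_export(
    stream: TextIO | str,
    kind: Literal["deaths", "population"],
    *,
    suppressed_token: str = DEFAULT_SUPPRESSED,
    on_suppressed: Literal["drop", "error"] = "drop",
) -> list[DeathStratum] | list[PopulationStratum]:
    """Parse a tab-delimited export into validated stratum records.

    Suppressed cells are dropped with a logged warning by default
    (``on_suppressed="error"`` raises instead).  ``Total`` rows and
    trailing notes lines are excluded.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if kind not in ("deaths", "population"):
        raise ValueError(f"kind must be 'deaths' or 'population', got {kind!r}")
    required = _DEATH_COLUMNS if kind == "deaths" else _POP_COLUMNS
    count_col = required[-1]

    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise WonderFormatError("empty export: no header row") from None
    cols = _header_map(header, required)

    records: list = []
    n_suppressed = 0
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) <= max(cols.values()):
            # trailing notes section: free text that no longer fits the grid
            break
        get = lambda c: row[cols[c]].strip()
        fields = {c: get(c) for c in required}
        if any(v.lower() == "total" for v in fields.values()):
            continue
        if not fields[count_col] and not fields["State"]:
            continue
        raw_count = fields[count_col]
        if raw_count == suppressed_token:
            if on_suppressed == "error":
                raise WonderValidationError(f"row {rownum}: suppressed cell")
            n_suppressed += 1
            continue
        try:
            count = int(raw_count.replace(",", ""))
        except ValueError:
            raise WonderValidationError(
                f"row {rownum}: non-numeric {count_col} value {raw_count!r}"
            ) from None
        if count < 0:
            raise WonderValidationError(f"row {rownum}: negative {count_col} {count}")
        try:
            year = int(fields["Year"])
            age = normalize_age_band(fields["Age Group"])
            sex = _SEX_ALIAS[fields["Sex"].lower()]
            if kind == "deaths":
                manner = _MANNER_ALIAS[fields["Manner"].lower()]
                records.append(
                    DeathStratum(
                        state=fields["State"],
                        year=year,
                        cause_code=fields["Cause Code"].upper(),
                        manner=manner,
                        age_group=age,
                        sex=sex,
                        deaths=count,
                    )
                )
            else:
                records.append(
                    PopulationStratum(
                        state=fields["State"], year=year, age_group=age,
                        sex=sex, population=count,
                    )
                )
        except (KeyError, ValueError) as exc:
            raise WonderValidationError(f"row {rownum}: {exc}") from None
    if n_suppressed:
        logger.warning("dropped %d suppressed cell(s) from %s export", n_suppressed, kind)
    return records


def write_records(
    records: Iterable[DeathStratum] | Iterable[PopulationStratum], stream: TextIO
) -> None:
    """Write records back out in the same tab-delimited dialect."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    if isinstance(records[0], DeathStratum):
        writer.writerow(_DEATH_COLUMNS)
        for r in records:
            writer.writerow(
                [r.state, r.year, r.cause_code, r.manner.value, r.age_group,
                 r.sex.value, r.deaths]
            )
    else:
        writer.writerow(_POP_COLUMNS)
        for r in records:
            writer.writerow([r.state, r.year, r.age_group, r.sex.value, r.population])


_SUMMARY_COLUMNS = [
    "jurisdiction", "period", "measure", "weighted_count", "crude_rate",
    "medical_millions", "work_loss_millions", "qol_loss_millions",
    "total_millions", "per_capita", "population",
    "count_display", "rate_display", "per_capita_display",
]

_CHANGE_COLUMNS = [
    "jurisdiction", "measure", "per_capita_start", "per_capita_end",
    "percent_change", "quintile", "region",
]


def write_summary_table(summaries, path) -> None:
    """Write summary or change-report rows as tab-delimited text.

    Monetary values are written at full precision; display-rounded columns
    (whole deaths, 0.1 rate, whole dollars per capita) are appended for
    summary rows.  Column order is fixed and documented in the module.
    """
    from .types import ChangeReport, StatePeriodSummary, round_half_away

    summaries = list(summaries)
    if not summaries:
        raise ValueError("refusing to write an empty summary table")
    rows = []
    if isinstance(summaries[0], StatePeriodSummary):
        for s in summaries:
            rows.append(
                [s.jurisdiction, s.period, s.measure, repr(s.weighted_count),
                 repr(s.crude_rate), repr(s.costs.medical), repr(s.costs.work_loss),
                 repr(s.costs.qol_loss), repr(s.costs.total), repr(s.per_capita),
                 repr(s.population), round_half_away(s.weighted_count),
                 f"{s.crude_rate:.1f}", round_half_away(s.per_capita)]
            )
        columns = _SUMMARY_COLUMNS
    elif isinstance(summaries[0], ChangeReport):
        for c in summaries:
            rows.append(
                [c.jurisdiction, c.measure, repr(c.per_capita_start),
                 repr(c.per_capita_end), c.percent_change,
                 "" if c.quintile is None else c.quintile, c.region or ""]
            )
        columns = _CHANGE_COLUMNS
    else:
        raise TypeError(f"unsupported row type {type(summaries[0]).__name__}")
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
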