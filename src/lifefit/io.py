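"""CSV / YAML round-tripping for cohorts, life tables and configs.

Cohort CSV dialect: header
``individual_id,strain,host,parent_pair,tree,sex,fate,event_day,pupal_weight,fecundity,offspring_sex_ratio``,
comma-separated UTF-8, empty field = absent value.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .records import (
    CSV_COLUMNS,
    Cohort,
    IndividualRecord,
    LifeTable,
    Treatment,
    validate_cohort,
)
from .simulate import GeneratorConfig


class CohortParseError(ValueError):
    """Raised when a cohort CSV fails parsing or validation."""


def _parse_row(row: dict, line_no: int) -> IndividualRecord:
    def opt(name, conv):
        raw = (row.get(name) or "").strip()
        if raw == "":
            return None
        try:
            return conv(raw)
        except ValueError:
            raise CohortParseError(
                f"row {line_no}: field {name!r} has non-numeric value {raw!r}"
            )

    try:
        event_day = int(row["event_day"])
    except (ValueError, TypeError):
        raise CohortParseError(
            f"row {line_no}: field 'event_day' must be an integer, "
            f"got {row.get('event_day')!r}"
        )
    return IndividualRecord(
        individual_id=row["individual_id"],
        strain=row["strain"],
        host=row["host"],
        parent_pair=row["parent_pair"],
        tree=row["tree"],
        sex=row["sex"],
        fate=row["fate"],
        event_day=event_day,
        pupal_weight=opt("pupal_weight", float),
        fecundity=opt("fecundity", lambda s: int(float(s))),
        offspring_sex_ratio=opt("offspring_sex_ratio", float),
    )


def read_cohort_csv(path: Union[str, Path]) -> Cohort:
    """Parse and validate one cohort CSV.

    Raises :class:`CohortParseError` naming the missing column, the
    offending row number, or every validation failure.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise CohortParseError(
                f"{path.name}: missing column(s) {', '.join(missing)}"
            )
        records = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    if not records:
        raise CohortParseError(f"{path.name}: no data rows")
    treatment = Treatment(records[0].strain, records[0].host)
    cohort = Cohort(treatment, records)
    problems = validate_cohort(cohort)
    if problems:
        raise CohortParseError(
            f"{path.name}: invalid cohort:\n  " + "\n  ".join(problems)
        )
    return cohort


def write_cohort_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.records:
            writer.writerow(
                [
                    r.individual_id,
                    r.strain,
                    r.host,
                    r.parent_pair,
                    r.tree,
                    r.sex,
                    r.fate,
                    r.event_day,
                    "" if r.pupal_weight is None else repr(r.pupal_weight),
                    "" if r.fecundity is None else r.fecundity,
                    "" if r.offspring_sex_ratio is None else repr(r.offspring_sex_ratio),
                ]
            )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in cohort.records], columns=CSV_COLUMNS)


def cohort_from_frame(frame: pd.DataFrame) -> Cohort:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"missing column(s) {', '.join(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            IndividualRecord(
                individual_id=str(row["individual_id"]),
                strain=row["strain"],
                host=row["host"],
                parent_pair=str(row["parent_pair"]),
                tree=str(row["tree"]),
                sex=row["sex"],
                fate=row["fate"],
                event_day=int(row["event_day"]),
                pupal_weight=None if pd.isna(row["pupal_weight"]) else float(row["pupal_weight"]),
                fecundity=None if pd.isna(row["fecundity"]) else int(row["fecundity"]),
                offspring_sex_ratio=(
                    None if pd.isna(row["offspring_sex_ratio"]) else float(row["offspring_sex_ratio"])
                ),
            )
        )
    treatment = Treatment(records[0].strain, records[0].host)
    return Cohort(treatment, records)


def write_life_table_csv(table: LifeTable, path: Union[str, Path]) -> None:
    pd.DataFrame({"age": table.ages, "lx": table.lx, "mx": table.mx}).to_csv(
        path, index=False
    )


def write_survivorship_csv(days, surv, path: Union[str, Path]) -> None:
    pd.DataFrame({"day": days, "surviving": surv}).to_csv(path, index=False)


def read_config(path: Union[str, Path]) -> GeneratorConfig:
    """Load a generator configuration from YAML."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    cfg = GeneratorConfig.from_dict(data)
    cfg.validate()
    return cfg


def write_config(config: GeneratorConfig, path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
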