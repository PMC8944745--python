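"""CSV / YAML readers and writers for the pipeline's tabular artifacts.

All tables round-trip through plain CSV with documented headers; dates are
ISO-8601.  Pedigree files are three columns (animal, sire, dam; 0 =
unknown) with tolerant header normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .datasets import TRAITS
from .pedigree import PedigreeTable
from .survival import CowRecords, SurvivalTable

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_records", "write_records",
    "read_survival_table", "write_survival_table",
    "read_matrix", "write_matrix",
    "read_yaml", "write_yaml",
]

_PED_ALIASES = {
    "animal": "animal", "animal_id": "animal", "id": "animal",
    "sire": "sire", "father": "sire", "sire_id": "sire",
    "dam": "dam", "mother": "dam", "dam_id": "dam",
}


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path)
    df.columns = [_PED_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    _require(df, ["animal", "sire", "dam"], "pedigree")
    return PedigreeTable.from_frame(df[["animal", "sire", "dam"]].fillna(0))


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.data.to_csv(path, index=False)


def _parse_dates(df: pd.DataFrame, col: str, what: str, allow_na: bool = False) -> pd.Series:
    raw = df[col]
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if not allow_na:
        bad = bad | raw.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{what}: malformed date {raw.iloc[row]!r} in column {col!r}, row {row}")
    return parsed


def read_records(cows_path, lactations_path, tests_path) -> CowRecords:
    cows = pd.read_csv(cows_path)
    _require(cows, ["animal_id", "herd_id", "first_calving_age_months"], "cows table")
    if "cull_date" in cows.columns:
        cows["cull_date"] = _parse_dates(cows, "cull_date", "cows table", allow_na=True)
    else:
        cows["cull_date"] = pd.NaT
    if "herd_active_until" in cows.columns:
        cows["herd_active_until"] = _parse_dates(cows, "herd_active_until", "cows table", allow_na=True)
    lact = pd.read_csv(lactations_path)
    _require(lact, ["animal_id", "parity", "calving_date"], "lactations table")
    lact["calving_date"] = _parse_dates(lact, "calving_date", "lactations table")
    tests = pd.read_csv(tests_path)
    _require(tests, ["animal_id", "parity", "dim"], "tests table")
    return CowRecords(cows=cows, lactations=lact, tests=tests)


def write_records(records: CowRecords, cows_path, lactations_path, tests_path) -> None:
    records.cows.to_csv(cows_path, index=False)
    records.lactations.to_csv(lactations_path, index=False)
    records.tests.to_csv(tests_path, index=False)


def read_survival_table(path) -> SurvivalTable:
    df = pd.read_csv(path)
    _require(df, ["animal_id", *TRAITS, "hy", "season", "fca", "censored"], "survival table")
    df["censored"] = df["censored"].astype(bool)
    return SurvivalTable(data=df)


def write_survival_table(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_matrix(M, path, labels=None) -> None:
    if isinstance(M, pd.DataFrame):
        M.to_csv(path)
    else:
        labels = list(labels) if labels is not None else [str(i) for i in range(len(M))]
        pd.DataFrame(np.asarray(M), index=labels, columns=labels).to_csv(path)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
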