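"""Synthea-dialect EHR tables: schemas, CSV round-trip I/O and date logic.

Five linked tables — patients, encounters, conditions, observations,
procedures — are held as :class:`pandas.DataFrame` objects with canonical
snake_case columns; on disk they use the Synthea CSV export headers
(``Id``, ``BIRTHDATE``, ``START`` ...).  All dates are calendar dates (no
time component) and every interval in this package is inclusive on both
ends.  Rows whose mandatory date fails to parse are dropped and counted
in a :class:`LoadReport`; referential-integrity violations are fatal.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

TABLES = ("patients", "encounters", "conditions", "observations", "procedures")
MANDATORY_TABLES = ("patients", "encounters", "conditions")

# canonical column -> on-disk CSV header, in on-disk column order
_CSV_COLUMNS: dict[str, list[tuple[str, str]]] = {
    "patients": [
        ("patient_id", "Id"),
        ("birth_date", "BIRTHDATE"),
        ("death_date", "DEATHDATE"),
        ("gender", "GENDER"),
        ("race", "RACE"),
        ("height_cm", "HEIGHT_CM"),
        ("weight_kg", "WEIGHT_KG"),
    ],
    "encounters": [
        ("encounter_id", "Id"),
        ("start_date", "START"),
        ("stop_date", "STOP"),
        ("patient_id", "PATIENT"),
        ("encounter_code", "CODE"),
        ("principal_diagnosis", "REASONCODE"),
    ],
    "conditions": [
        ("onset_date", "START"),
        ("end_date", "STOP"),
        ("patient_id", "PATIENT"),
        ("encounter_id", "ENCOUNTER"),
        ("code", "CODE"),
    ],
    "observations": [
        ("obs_date", "DATE"),
        ("patient_id", "PATIENT"),
        ("code", "CODE"),
        ("value", "VALUE"),
        ("units", "UNITS"),
    ],
    "procedures": [
        ("proc_date", "DATE"),
        ("patient_id", "PATIENT"),
        ("code", "CODE"),
    ],
}

#: Header remapping for Synthea releases whose column names drift from the
#: dialect above.  Keys are folded to upper case before lookup.
COLUMN_ALIASES: dict[str, str] = {
    "ID": "Id",
    "BIRTH_DATE": "BIRTHDATE",
    "DEATH_DATE": "DEATHDATE",
    "REASON_CODE": "REASONCODE",
    "PATIENT_ID": "PATIENT",
    "ENCOUNTER_ID": "ENCOUNTER",
}

# date columns per table; True = mandatory (row dropped when unparseable)
_DATE_COLUMNS: dict[str, dict[str, bool]] = {
    "patients": {"birth_date": True, "death_date": False},
    "encounters": {"start_date": True, "stop_date": False},
    "conditions": {"onset_date": True, "end_date": False},
    "observations": {"obs_date": True},
    "procedures": {"proc_date": True},
}

_FLOAT_COLUMNS: dict[str, list[str]] = {
    "patients": ["height_cm", "weight_kg"],
    "observations": ["value"],
}

_GENDER_MAP = {"M": "male", "F": "female", "MALE": "male", "FEMALE": "female",
               "male": "male", "female": "female"}


class LoadError(IOError):
    """A mandatory table file is missing or unreadable."""


class CohortIntegrityError(ValueError):
    """Referential-integrity or uniqueness violations in a cohort."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort integrity violations:\n  " + "\n  ".join(self.problems))


@dataclasses.dataclass
class LoadReport:
    """Bookkeeping of rows dropped or repaired while reading a cohort."""

    rows_dropped: dict[str, int] = dataclasses.field(default_factory=dict)
    messages: list[str] = dataclasses.field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return sum(self.rows_dropped.values())

    def summary(self) -> str:
        lines = [f"rows dropped: {self.total_dropped}"]
        lines += [f"  {t}: {n}" for t, n in sorted(self.rows_dropped.items())]
        lines += self.messages
        return "\n".join(lines)


def _parse_float(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def _string_columns(table: str) -> list[str]:
    dates = set(_DATE_COLUMNS[table])
    floats = set(_FLOAT_COLUMNS.get(table, []))
    return [c for c, _ in _CSV_COLUMNS[table] if c not in dates and c not in floats]


def _normalize_table(table: str, df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw frame to the canonical column order and dtypes."""
    out = pd.DataFrame(index=df.index if len(df) else None)
    for col, _ in _CSV_COLUMNS[table]:
        s = df[col] if col in df.columns else pd.Series(pd.NA, index=out.index, dtype="object")
        if col in _DATE_COLUMNS[table]:
            if not pd.api.types.is_datetime64_any_dtype(s):
                sample = s.dropna()
                if len(sample) and isinstance(sample.iloc[0], str):
                    # ISO-8601 strings, with or without a time component
                    s = pd.to_datetime(s, format="ISO8601", errors="coerce", utc=True)
                else:  # date / datetime objects (or all-absent)
                    s = pd.to_datetime(s, errors="coerce")
            if getattr(s.dt, "tz", None) is not None:
                s = s.dt.tz_localize(None)
            s = s.dt.normalize()
        elif col in _FLOAT_COLUMNS.get(table, []):
            if pd.api.types.is_numeric_dtype(s):
                s = s.astype(float)
            else:  # exact strtod so repr-serialized floats round-trip bit-for-bit
                s = pd.to_numeric(s.map(_parse_float, na_action="ignore"), errors="coerce")
                s = s.astype(float)
        else:
            s = s.astype("string")
            if col == "gender":
                s = s.map(lambda g: _GENDER_MAP.get(g, g), na_action="ignore").astype("string")
        out[col] = s
    return out.reset_index(drop=True)


def empty_table(table: str) -> pd.DataFrame:
    return _normalize_table(table, pd.DataFrame(columns=[c for c, _ in _CSV_COLUMNS[table]]))


@dataclasses.dataclass
class EhrCohort:
    """The five linked EHR tables of one (synthetic or real) population."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    conditions: pd.DataFrame
    observations: pd.DataFrame
    procedures: pd.DataFrame
    load_report: LoadReport = dataclasses.field(default_factory=LoadReport)

    @classmethod
    def empty(cls) -> "EhrCohort":
        return cls(*(empty_table(t) for t in TABLES))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> list[str]:
        return validate_cohort(self)

    def equals(self, other: "EhrCohort") -> bool:
        return all(self.table(t).equals(other.table(t)) for t in TABLES)


def make_cohort(patients=None, encounters=None, conditions=None,
                observations=None, procedures=None, validate: bool = True) -> EhrCohort:
    """Build a normalized cohort from frames or lists of row dicts.

    Raises :class:`CohortIntegrityError` when ``validate`` is set and any
    foreign key fails to resolve or a patient id repeats.
    """
    frames = {}
    for name, data in zip(TABLES, (patients, encounters, conditions, observations, procedures)):
        if data is None:
            frames[name] = empty_table(name)
        else:
            df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
            frames[name] = _normalize_table(name, df)
    cohort = EhrCohort(**frames)
    if validate:
        problems = validate_cohort(cohort)
        if problems:
            raise CohortIntegrityError(problems)
    return cohort


def validate_cohort(cohort: EhrCohort) -> list[str]:
    """Referential-integrity report; empty iff every invariant holds."""
    problems: list[str] = []
    pats = cohort.patients
    dup = pats["patient_id"][pats["patient_id"].duplicated()].unique()
    if len(dup):
        problems.append(f"duplicate patient_id: {sorted(map(str, dup))}")
    dup_e = cohort.encounters["encounter_id"][cohort.encounters["encounter_id"].duplicated()].unique()
    if len(dup_e):
        problems.append(f"duplicate encounter_id: {sorted(map(str, dup_e))}")

    known_p = set(pats["patient_id"].dropna())
    for table in ("encounters", "conditions", "observations", "procedures"):
        refs = cohort.table(table)["patient_id"].dropna()
        orphans = sorted(set(refs) - known_p)
        if orphans:
            problems.append(f"{table}: unknown patient_id {orphans}")
    known_e = set(cohort.encounters["encounter_id"].dropna())
    cond_refs = cohort.conditions["encounter_id"].dropna()
    orphan_enc = sorted(set(cond_refs) - known_e)
    if orphan_enc:
        problems.append(f"conditions: unknown encounter_id {orphan_enc}")

    bad = pats["death_date"].notna() & (pats["death_date"] < pats["birth_date"])
    if bad.any():
        problems.append(f"patients: death_date before birth_date for {sorted(pats.loc[bad, 'patient_id'])}")
    enc = cohort.encounters
    bad = enc["stop_date"].notna() & (enc["stop_date"] < enc["start_date"])
    if bad.any():
        problems.append(f"encounters: stop_date before start_date for {sorted(enc.loc[bad, 'encounter_id'])}")
    con = cohort.conditions
    bad = con["end_date"].notna() & (con["end_date"] < con["onset_date"])
    if bad.any():
        problems.append(f"conditions: end_date before onset_date ({int(bad.sum())} rows)")
    return problems


def _rename_map(table: str) -> dict[str, str]:
    m = {csv.upper(): canon for canon, csv in _CSV_COLUMNS[table]}
    for alias, target in COLUMN_ALIASES.items():
        if target.upper() in m:
            m.setdefault(alias, m[target.upper()])
    return m


def read_cohort(directory_path) -> EhrCohort:
    """Read a cohort from a directory of Synthea-dialect CSV files.

    ``patients.csv``, ``encounters.csv`` and ``conditions.csv`` are
    mandatory; missing ``observations.csv``/``procedures.csv`` are
    substituted by empty tables.  Rows with unparseable mandatory dates
    are dropped and counted in ``cohort.load_report``.
    """
    directory = Path(directory_path)
    report = LoadReport()
    frames: dict[str, pd.DataFrame] = {}
    for table in TABLES:
        path = directory / f"{table}.csv"
        if not path.exists():
            if table in MANDATORY_TABLES:
                raise LoadError(f"missing mandatory table file: {path}")
            frames[table] = empty_table(table)
            continue
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        rename = _rename_map(table)
        raw.columns = [rename.get(str(c).strip().upper(), str(c).strip()) for c in raw.columns]
        raw = raw.replace("", pd.NA)
        df = _normalize_table(table, raw)
        keep = pd.Series(True, index=df.index)
        for col, mandatory in _DATE_COLUMNS[table].items():
            had_value = raw[col].notna() if col in raw.columns else pd.Series(False, index=df.index)
            bad = df[col].isna() & had_value
            if mandatory:
                missing = df[col].isna()
                if missing.any():
                    keep &= ~missing
                    report.messages.append(
                        f"{table}: dropped {int(missing.sum())} rows with missing/unparseable {col}")
            elif bad.any():
                report.messages.append(
                    f"{table}: {int(bad.sum())} unparseable {col} values treated as absent")
        dropped = int((~keep).sum())
        if dropped:
            report.rows_dropped[table] = dropped
        frames[table] = df.loc[keep].reset_index(drop=True)
    cohort = EhrCohort(**frames, load_report=report)
    problems = validate_cohort(cohort)
    if problems:
        raise CohortIntegrityError(problems)
    return cohort


def _format_float(v) -> str:
    return "" if pd.isna(v) else repr(float(v))


def write_cohort(cohort: EhrCohort, directory_path) -> list[Path]:
    """Write the five CSV files; absent values become empty fields.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` field-for-field
    (floats are serialized with shortest round-trip ``repr``).
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for table in TABLES:
        df = cohort.table(table)
        out = pd.DataFrame(index=df.index)
        for col, header in _CSV_COLUMNS[table]:
            s = df[col]
            if col in _DATE_COLUMNS[table]:
                out[header] = s.dt.strftime("%Y-%m-%d").fillna("")
            elif col in _FLOAT_COLUMNS.get(table, []):
                out[header] = s.map(_format_float)
            else:
                out[header] = s.astype(object).where(s.notna(), "")
        path = directory / f"{table}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# date logic


def as_date(x) -> dt.date:
    """Coerce a Timestamp / datetime / ISO string to a plain date."""
    if isinstance(x, pd.Timestamp):
        return x.date()
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def compute_age(birth_date, as_of_date) -> int:
    """Completed years at ``as_of_date`` under the birthday-anniversary rule."""
    b, a = as_date(birth_date), as_date(as_of_date)
    if a < b:
        raise ValueError(f"as_of_date {a} precedes birth_date {b}")
    years = a.year - b.year
    if (a.month, a.day) < (b.month, b.day):
        years -= 1
    return years


def ages_at(birth_dates: pd.Series, as_of_date) -> pd.Series:
    """Vectorized :func:`compute_age` over a datetime64 Series."""
    a = as_date(as_of_date)
    b = birth_dates
    before_anniv = (b.dt.month > a.month) | ((b.dt.month == a.month) & (b.dt.day > a.day))
    return a.year - b.dt.year - before_anniv.astype(int)


def is_condition_active(onset_date, end_date, date) -> bool:
    """True iff ``onset <= date`` and the condition has not ended before ``date``.

    Boundaries are inclusive at both onset and end; an absent end date
    means the condition is still active.
    """
    d = as_date(date)
    if onset_date is None or pd.isna(onset_date):
        return False
    if as_date(onset_date) > d:
        return False
    if end_date is None or pd.isna(end_date):
        return True
    return d <= as_date(end_date)


def years_ago(date_, n_years: int) -> dt.date:
    """The calendar anniversary ``n_years`` before ``date_`` (Feb 29 -> Feb 28)."""
    d = as_date(date_)
    try:
        return d.replace(year=d.year - n_years)
    except ValueError:  # Feb 29 in a non-leap target year
        return d.replace(year=d.year - n_years, day=28)
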