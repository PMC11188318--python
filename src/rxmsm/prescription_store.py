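"""Data model, ATC code catalog, and flat-file I/O for prescription databases.

A prescription database is two delimited tables: a patients table
(``patient_id, sex, birth_date``) and a dispensing records table
(``patient_id, dispense_date, atc_code, days_covered``).  Dates are ISO-8601
at the file boundary and integer day offsets (days since 1970-01-01)
everywhere inside the package, so that all interval arithmetic is exact.

The :class:`CodeCatalog` maps WHO ATC codes to the roles the analysis cares
about -- the five antihypertensive monotherapy classes, the acute
cardiac-drug-therapy (CDT) outcome proxy codes, fixed-dose combinations,
chronic-therapy exclusion sets, and comorbidity drug sets used as
time-varying confounders.  Matching is by code prefix at ATC levels 3-5.
"""

from __future__ import annotations

import datetime as _dt
import io
import re
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EPOCH",
    "to_day",
    "from_day",
    "ATC_PATTERN",
    "is_valid_atc",
    "EXPOSURE_CLASSES",
    "Role",
    "CodeCatalog",
    "CatalogError",
    "DatabaseFormatError",
    "PrescriptionDatabase",
    "read_database",
    "write_database",
    "write_table",
    "read_table",
    "load_config",
    "dump_config",
]

# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

EPOCH = _dt.date(1970, 1, 1)


def to_day(value) -> int:
    """Convert an ISO date string or ``datetime.date`` to an integer day offset."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, str):
        value = _dt.date.fromisoformat(value)
    if isinstance(value, _dt.datetime):
        value = value.date()
    return (value - EPOCH).days


def from_day(day: int) -> _dt.date:
    """Convert an integer day offset back to a calendar date."""
    return EPOCH + _dt.timedelta(days=int(day))


def year_of_day(day: int) -> int:
    return from_day(day).year


def age_at(birth_day: int, on_day: int) -> int:
    """Completed years of age on ``on_day`` for someone born on ``birth_day``."""
    b, d = from_day(birth_day), from_day(on_day)
    years = d.year - b.year
    if (d.month, d.day) < (b.month, b.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# ATC codes
# ---------------------------------------------------------------------------

# Level 2 (A10), level 3 (A10B), level 4 (A10BA), level 5 (A10BA02).
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")


def is_valid_atc(code: str) -> bool:
    return isinstance(code, str) and bool(ATC_PATTERN.match(code))


#: The five antihypertensive monotherapy classes and their ATC prefixes.
EXPOSURE_CLASSES: dict[str, tuple[str, ...]] = {
    "ACEI": ("C09A",),
    "ARB": ("C09C",),
    "BB": ("C07A",),
    "CCB": ("C08C", "C08D", "C08E"),
    "THIAZIDE": ("C03AA",),
}

CLASS_LABELS: tuple[str, ...] = ("BB", "ACEI", "ARB", "CCB", "THIAZIDE")  # BB first = reference


@dataclass(frozen=True)
class Role:
    """Role of an ATC code in the analysis.

    ``kind`` is one of ``exposure | outcome | antihyperlipidemic |
    fixed_combination | exclusion_therapy | comorbidity | other``;
    ``name`` carries the class label / named set where applicable.
    """

    kind: str
    name: str | None = None

    def __str__(self) -> str:  # e.g. "exposure:BB", "comorbidity:diabetes"
        return self.kind if self.name is None else f"{self.kind}:{self.name}"


OTHER = Role("other")


class CatalogError(ValueError):
    """Raised when a code catalog is internally inconsistent."""


@dataclass
class CodeCatalog:
    """Configurable ATC prefix catalog.

    Default exclusion-therapy and comorbidity sets are drawn from the standard
    ATC chapters for each indication and are fully overridable through the run
    configuration: the published source for the analysis design does not fix
    them, so they are parameters of the pipeline rather than constants.
    """

    outcome_prefixes: tuple[str, ...] = ("B01AC", "C01DA", "B01AA", "C01DX")
    antihyperlipidemic_prefixes: tuple[str, ...] = ("C10A",)
    fixed_combination_prefixes: tuple[str, ...] = (
        "C03AB", "C03EA", "C07B", "C07C", "C07D", "C07F", "C08G", "C09B", "C09D", "C10B",
    )
    exclusion_therapy_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "heart_failure": ("C01AA",),        # cardiac glycosides
            "migraine": ("N02C",),              # antimigraine preparations
            "adrenal_disease": ("H02AA",),      # mineralocorticoids
            "hyperparathyroidism": ("H05B",),   # anti-parathyroid agents
            "thyroid": ("H03A", "H03B"),        # thyroid therapy / antithyroid
        }
    )
    comorbidity_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "diabetes": ("A10",),
            "ra": ("M01C", "L04A"),
            "asthma_copd": ("R03",),
        }
    )

    def __post_init__(self):
        self._prefix_role: dict[str, Role] = {}
        for cls, prefixes in EXPOSURE_CLASSES.items():
            for p in prefixes:
                self._add(p, Role("exposure", cls))
        for p in self.outcome_prefixes:
            self._add(p, Role("outcome"))
        for p in self.antihyperlipidemic_prefixes:
            self._add(p, Role("antihyperlipidemic"))
        for p in self.fixed_combination_prefixes:
            self._add(p, Role("fixed_combination"))
        for name, prefixes in self.exclusion_therapy_prefixes.items():
            for p in prefixes:
                self._add(p, Role("exclusion_therapy", name))
        for name, prefixes in self.comorbidity_prefixes.items():
            for p in prefixes:
                self._add(p, Role("comorbidity", name))
        self._validate_disjoint()
        self._max_len = max(len(p) for p in self._prefix_role)

    def _add(self, prefix: str, role: Role) -> None:
        if not is_valid_atc(prefix):
            raise CatalogError(f"invalid ATC prefix in catalog: {prefix!r}")
        existing = self._prefix_role.get(prefix)
        if existing is not None and existing != role:
            raise CatalogError(
                f"prefix {prefix} assigned to both {existing} and {role}"
            )
        self._prefix_role[prefix] = role

    def _validate_disjoint(self) -> None:
        # One code must never match two different roles: forbid any prefix that
        # is a string prefix of another prefix carrying a different role.
        prefixes = sorted(self._prefix_role)
        for i, a in enumerate(prefixes):
            for b in prefixes[i + 1 :]:
                if b.startswith(a) and self._prefix_role[a] != self._prefix_role[b]:
                    raise CatalogError(
                        f"overlapping prefixes {a} ({self._prefix_role[a]}) and "
                        f"{b} ({self._prefix_role[b]}) map to different roles"
                    )

    # -- queries ------------------------------------------------------------

    def classify(self, code: str) -> Role:
        """Longest-prefix role lookup; ``Role('other')`` when nothing matches."""
        for ln in range(min(len(code), self._max_len), 0, -1):
            role = self._prefix_role.get(code[:ln])
            if role is not None:
                return role
        return OTHER

    def exposure_class(self, code: str) -> str | None:
        role = self.classify(code)
        return role.name if role.kind == "exposure" else None

    def role_series(self, codes: pd.Series) -> pd.Series:
        """Vectorized classification of a code series; returns 'kind:name' strings."""
        uniq = codes.unique()
        mapping = {c: str(self.classify(c)) for c in uniq}
        return codes.map(mapping)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome_prefixes": sorted(self.outcome_prefixes),
            "antihyperlipidemic_prefixes": sorted(self.antihyperlipidemic_prefixes),
            "fixed_combination_prefixes": sorted(self.fixed_combination_prefixes),
            "exclusion_therapy_prefixes": {
                k: sorted(v) for k, v in sorted(self.exclusion_therapy_prefixes.items())
            },
            "comorbidity_prefixes": {
                k: sorted(v) for k, v in sorted(self.comorbidity_prefixes.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeCatalog":
        kwargs = {}
        valid = {f.name for f in _dc_fields(cls)}
        for key, value in d.items():
            if key not in valid:
                raise CatalogError(f"unknown catalog key: {key}")
            if isinstance(value, dict):
                kwargs[key] = {k: tuple(v) for k, v in value.items()}
            else:
                kwargs[key] = tuple(value)
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CodeCatalog":
        return cls.from_dict(yaml.safe_load(text))


def classify_atc(code: str, catalog: CodeCatalog) -> Role:
    """Classify a single ATC code against the catalog (pure function)."""
    if not is_valid_atc(code):
        raise ValueError(f"invalid ATC code: {code!r}")
    return catalog.classify(code)


# ---------------------------------------------------------------------------
# Database container and readers
# ---------------------------------------------------------------------------


class DatabaseFormatError(ValueError):
    """Raised for malformed input files; the message names the offending row."""


PATIENT_COLUMNS = ["patient_id", "sex", "birth_date"]
RECORD_COLUMNS = ["patient_id", "dispense_date", "atc_code", "days_covered"]


@dataclass
class PrescriptionDatabase:
    """Validated in-memory prescription database.

    ``patients``: patient_id, sex, birth_date, birth_day.
    ``records``: patient_id, dispense_date, atc_code, days_covered, day;
    sorted by (patient_id, day), with ``day`` the integer offset of
    ``dispense_date``.
    """

    patients: pd.DataFrame
    records: pd.DataFrame

    def records_for(self, patient_id: str) -> pd.DataFrame:
        return self.records[self.records["patient_id"] == patient_id]

    def __len__(self) -> int:
        return len(self.records)


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise DatabaseFormatError(
            f"malformed {what} {series.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
            f"at line {row}"
        )
    return (parsed - pd.Timestamp(EPOCH)).dt.days.astype(np.int64)


def _require_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise DatabaseFormatError(
            f"{what} file: missing columns {missing}, unknown columns {unknown}"
        )


def read_database(path, catalog: CodeCatalog | None = None) -> PrescriptionDatabase:
    """Read and validate a prescription database.

    ``path`` is a directory containing ``patients.csv`` and ``records.csv``.
    Records come back sorted by (patient_id, dispense_date) with the input
    multiset of rows preserved.  Any malformed value raises
    :class:`DatabaseFormatError` naming the file line.
    """
    from pathlib import Path

    path = Path(path)
    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str, "sex": str})
    records = pd.read_csv(
        path / "records.csv", dtype={"patient_id": str, "atc_code": str}
    )
    return validate_database(patients, records, catalog)


def validate_database(
    patients: pd.DataFrame, records: pd.DataFrame, catalog: CodeCatalog | None = None
) -> PrescriptionDatabase:
    patients = patients.copy()
    records = records.copy()
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    _require_columns(records, RECORD_COLUMNS, "records")

    if patients["patient_id"].duplicated().any():
        dup = patients["patient_id"][patients["patient_id"].duplicated()].iloc[0]
        raise DatabaseFormatError(f"duplicate patient_id {dup!r} in patients file")
    bad_sex = ~patients["sex"].isin(["male", "female"])
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise DatabaseFormatError(
            f"invalid sex {patients['sex'].iloc[i]!r} at line {i + 2} of patients file"
        )
    patients["birth_day"] = _parse_dates(patients["birth_date"], "birth_date")

    records["day"] = _parse_dates(records["dispense_date"], "dispense_date")
    bad_atc = ~records["atc_code"].map(is_valid_atc)
    if bad_atc.any():
        i = int(np.flatnonzero(bad_atc.to_numpy())[0])
        raise DatabaseFormatError(
            f"invalid ATC code {records['atc_code'].iloc[i]!r} at line {i + 2} of records file"
        )
    dc = pd.to_numeric(records["days_covered"], errors="coerce")
    bad_dc = dc.isna() | (dc < 1) | (dc != dc.round())
    if bad_dc.any():
        i = int(np.flatnonzero(bad_dc.to_numpy())[0])
        raise DatabaseFormatError(
            f"invalid days_covered {records['days_covered'].iloc[i]!r} at line "
            f"{i + 2} of records file"
        )
    records["days_covered"] = dc.astype(np.int64)

    unknown = ~records["patient_id"].isin(patients["patient_id"])
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise DatabaseFormatError(
            f"unknown patient_id {records['patient_id'].iloc[i]!r} at line "
            f"{i + 2} of records file"
        )

    merged = records.merge(patients[["patient_id", "birth_day"]], on="patient_id")
    born_late = merged["day"] <= merged["birth_day"]
    if born_late.any():
        pid = merged["patient_id"][born_late].iloc[0]
        raise DatabaseFormatError(
            f"patient {pid!r} has a dispensing on or before their birth date"
        )

    records = records.sort_values(["patient_id", "day"], kind="mergesort").reset_index(
        drop=True
    )
    patients = patients.reset_index(drop=True)
    return PrescriptionDatabase(patients=patients, records=records)


def write_database(db: PrescriptionDatabase, path) -> None:
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_table(db.patients[PATIENT_COLUMNS], path / "patients.csv")
    write_table(db.records[RECORD_COLUMNS + ["day"]].drop(columns="day"), path / "records.csv")


# ---------------------------------------------------------------------------
# Generic derived-table I/O
# ---------------------------------------------------------------------------

_NA_SENTINEL = "NA"


def write_table(rows: pd.DataFrame, path, allow_empty: bool = True) -> None:
    """Write a derived table as CSV with deterministic column order.

    Missing values are written as the sentinel ``NA`` and recovered by
    :func:`read_table`; the round trip is lossless for strings, integers,
    floats (full repr precision) and booleans.
    """
    if len(rows) == 0 and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path}")
    rows.to_csv(path, index=False, na_rep=_NA_SENTINEL)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, na_values=[_NA_SENTINEL], keep_default_na=False, dtype_backend="numpy_nullable"
    ).convert_dtypes()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def load_config(path_or_text) -> dict:
    """Load the YAML run configuration (catalog, rules, simulation, analysis)."""
    if isinstance(path_or_text, (str,)) and "\n" in path_or_text:
        return yaml.safe_load(io.StringIO(path_or_text)) or {}
    with open(path_or_text) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
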