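"""Patient records, cohorts, CSV I/O and cohort-level filtering.

A :class:`Cohort` is an ordered collection of :class:`PatientRecord`
objects — one subject per record, with demographics, serum markers,
auxiliary labs and (optionally) a measured GFR.  All downstream stages
(equation evaluation, model development, evaluation) operate on cohorts.

Units are fixed by convention and taken at face value on input:

========  =====================  =================
field     meaning                unit
========  =====================  =================
age       age at visit           years
scr       serum creatinine       mg/dL
scys      serum cystatin C       mg/L
bmi       body mass index        kg/m^2
bun       blood urea nitrogen    mg/dL
alb       serum albumin          g/dL
ua        uric acid              mg/dL
hgb       hemoglobin             g/dL
mgfr      measured GFR           mL/min/1.73 m^2
========  =====================  =================

Hemoglobin is stored in g/dL (values around 12); creatinine reported in
µmol/L can be converted on read with ``scr_umol_per_l=True`` (÷88.4).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "PatientRecord",
    "Cohort",
    "CohortError",
    "ConfigurationError",
    "RowError",
    "SCR_UMOL_PER_MGDL",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "complete_case",
    "temporal_split",
    "random_split",
]

#: conversion factor: serum creatinine mg/dL -> µmol/L
SCR_UMOL_PER_MGDL = 88.4

#: canonical CSV column order
CSV_COLUMNS = [
    "subject_id",
    "visit_date",
    "age",
    "sex",
    "scr",
    "scys",
    "bmi",
    "bun",
    "alb",
    "ua",
    "hgb",
    "mgfr",
    "exclusion_flags",
]

#: fields that must be strictly positive when present
_POSITIVE_FIELDS = ("scr", "scys", "bun", "mgfr")

#: numeric per-subject fields, in canonical order
NUMERIC_FIELDS = ("age", "scr", "scys", "bmi", "bun", "alb", "ua", "hgb", "mgfr")


class CohortError(Exception):
    """Base class for cohort-level errors."""


class ConfigurationError(CohortError):
    """A caller-supplied column mapping, field name or option is invalid."""


class RowError(CohortError):
    """One or more input rows violate the record invariants.

    Carries ``rows``: a list of ``(row_number, message)`` pairs, with row
    numbers counted from 1 for the first data row of the file.
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"row {i}: {msg}" for i, msg in rows)
        super().__init__(f"{len(rows)} invalid row(s): {detail}")


class Sex(enum.Enum):
    FEMALE = "F"
    MALE = "M"

    @classmethod
    def parse(cls, value) -> "Sex":
        """Parse ``"F"``/``"M"`` (case-insensitive) or 0/1 (1 = male)."""
        if isinstance(value, Sex):
            return value
        if isinstance(value, (int, np.integer)) and value in (0, 1):
            return cls.MALE if value == 1 else cls.FEMALE
        s = str(value).strip().upper()
        if s in ("F", "FEMALE", "0"):
            return cls.FEMALE
        if s in ("M", "MALE", "1"):
            return cls.MALE
        raise ValueError(f"cannot parse sex value {value!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics, labs and optional measured GFR."""

    subject_id: str
    age: float
    sex: Sex
    scr: float | None = None
    scys: float | None = None
    bmi: float | None = None
    bun: float | None = None
    alb: float | None = None
    ua: float | None = None
    hgb: float | None = None
    mgfr: float | None = None
    visit_date: _dt.date | None = None
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    def get(self, name: str):
        if name == "sex":
            return self.sex
        return getattr(self, name)

    def replace(self, **kw) -> "PatientRecord":
        return dataclasses.replace(self, **kw)


class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique subject ids."""

    def __init__(self, records: Iterable[PatientRecord], label: str = "",
                 provenance: str = ""):
        self.records: list[PatientRecord] = list(records)
        self.label = label
        self.provenance = provenance
        seen: set[str] = set()
        for r in self.records:
            if r.subject_id in seen:
                raise CohortError(f"duplicate subject_id {r.subject_id!r}")
            seen.add(r.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def with_records(self, records: Iterable[PatientRecord],
                     label: str | None = None) -> "Cohort":
        return Cohort(records, label=self.label if label is None else label,
                      provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical column names (sex as ``"F"``/``"M"``)."""
        rows = []
        for r in self.records:
            rows.append({
                "subject_id": r.subject_id,
                "visit_date": r.visit_date.isoformat() if r.visit_date else None,
                "age": r.age,
                "sex": r.sex.value,
                "scr": r.scr,
                "scys": r.scys,
                "bmi": r.bmi,
                "bun": r.bun,
                "alb": r.alb,
                "ua": r.ua,
                "hgb": r.hgb,
                "mgfr": r.mgfr,
                "exclusion_flags": ";".join(sorted(r.exclusion_flags)) or None,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def column(self, name: str) -> np.ndarray:
        """Numeric column as a float array (NaN where missing)."""
        if name == "sex":
            return np.array([1.0 if r.sex is Sex.MALE else 0.0 for r in self.records])
        return np.array(
            [np.nan if r.get(name) is None else float(r.get(name)) for r in self.records]
        )


def _parse_cell(value, name: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip().replace("−", "-")  # unicode minus
        if value == "":
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable numeric value {value!r} in column {name!r}")


def read_cohort(path: str | Path, column_map: Mapping[str, str] | None = None,
                label: str = "", scr_umol_per_l: bool = False) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Canonical column names are listed in
        :data:`CSV_COLUMNS`; non-canonical headers can be renamed with
        ``column_map`` (maps *file* column name to canonical name).
    scr_umol_per_l
        If true, the creatinine column is in µmol/L and is divided by
        88.4 to obtain mg/dL.

    Raises
    ------
    ConfigurationError
        if a mandatory column (age, sex, scr, scys) is absent.
    RowError
        listing every row that violates a record invariant (positivity,
        unparsable numbers, bad sex codes).  Rows are never silently
        dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("age", "sex", "scr", "scys"):
        if col not in df.columns:
            raise ConfigurationError(f"mandatory column {col!r} missing "
                                     f"(have: {list(df.columns)})")

    records: list[PatientRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            kw: dict = {}
            sid = row.get("subject_id")
            kw["subject_id"] = str(sid) if sid is not None and not (
                isinstance(sid, float) and math.isnan(sid)) else f"row{i}"
            kw["sex"] = Sex.parse(row["sex"])
            for name in NUMERIC_FIELDS:
                if name in df.columns:
                    kw[name] = _parse_cell(row.get(name), name)
            if kw.get("age") is None:
                raise ValueError("age is missing")
            if scr_umol_per_l and kw.get("scr") is not None:
                kw["scr"] = kw["scr"] / SCR_UMOL_PER_MGDL
            vd = row.get("visit_date")
            if vd is not None and isinstance(vd, str) and vd.strip():
                kw["visit_date"] = _dt.date.fromisoformat(vd.strip())
            flags = row.get("exclusion_flags")
            if flags is not None and isinstance(flags, str) and flags.strip():
                kw["exclusion_flags"] = frozenset(
                    f.strip() for f in flags.split(";") if f.strip())
            records.append(PatientRecord(**kw))
        except ValueError as exc:
            bad.append((i, str(exc)))
    if bad:
        raise RowError(bad)
    return Cohort(records, label=label or path.stem, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical dialect (full precision)."""
    df = cohort.to_frame()
    # repr-roundtrip floats so read_cohort(write_cohort(c)) is the identity
    for col in NUMERIC_FIELDS:
        df[col] = df[col].map(lambda v: repr(float(v)) if v is not None and
                              not (isinstance(v, float) and math.isnan(v)) else None)
    df.to_csv(path, index=False)


def apply_exclusions(cohort: Cohort, min_age: float = 18.0
                     ) -> tuple[Cohort, dict[str, int]]:
    """Remove subjects aged under ``min_age`` or carrying any exclusion flag.

    Exclusion flags stand for clinical criteria that cannot be computed
    from labs (dialysis, trimethoprim/cimetidine use, acute kidney
    function deterioration, ...); they are supplied by the caller.

    Returns the filtered cohort and a per-reason removal count (a subject
    excluded for several reasons is counted once under each).
    """
    counts: dict[str, int] = {}
    kept: list[PatientRecord] = []
    for r in cohort:
        reasons = []
        if r.age < min_age:
            reasons.append(f"age<{min_age:g}")
        reasons.extend(sorted(r.exclusion_flags))
        if reasons:
            for reason in reasons:
                counts[reason] = counts.get(reason, 0) + 1
        else:
            kept.append(r)
    return cohort.with_records(kept), counts


def complete_case(cohort: Cohort, required_vars: Sequence[str]
                  ) -> tuple[Cohort, int]:
    """Retain only records with every ``required_vars`` field present.

    Missing data are never imputed; this is a complete-case analysis.
    Returns the filtered cohort and the number of records removed.
    """
    valid = set(NUMERIC_FIELDS) | {"sex", "visit_date", "subject_id"}
    for name in required_vars:
        if name not in valid:
            raise ConfigurationError(f"unknown field name {name!r}")
    kept = [r for r in cohort
            if all(r.get(name) is not None for name in required_vars)]
    return cohort.with_records(kept), len(cohort) - len(kept)


def temporal_split(cohort: Cohort, cutoff: _dt.date | str
                   ) -> tuple[Cohort, Cohort]:
    """Split by visit date: development = visits on or before ``cutoff``.

    Every record must carry a visit date; offenders are reported by
    subject id.  The cutoff is inclusive on the development side.
    """
    if isinstance(cutoff, str):
        cutoff = _dt.date.fromisoformat(cutoff)
    missing = [r.subject_id for r in cohort if r.visit_date is None]
    if missing:
        raise CohortError(f"records missing visit_date: {missing}")
    dev = [r for r in cohort if r.visit_date <= cutoff]
    val = [r for r in cohort if r.visit_date > cutoff]
    return (cohort.with_records(dev, label="development"),
            cohort.with_records(val, label="validation"))


def random_split(cohort: Cohort, dev_fraction: float, seed: int
                 ) -> tuple[Cohort, Cohort]:
    """Seeded random split into development/validation cohorts.

    Development size is ``round(n * dev_fraction)``; the partition is a
    deterministic function of ``seed`` and preserves within-group record
    order.
    """
    if not 0 < dev_fraction < 1:
        raise ConfigurationError("dev_fraction must be in (0, 1)")
    n = len(cohort)
    n_dev = int(round(n * dev_fraction))
    rng = np.random.default_rng(seed)
    dev_idx = set(rng.choice(n, size=n_dev, replace=False).tolist())
    dev = [r for i, r in enumerate(cohort) if i in dev_idx]
    val = [r for i, r in enumerate(cohort) if i not in dev_idx]
    return (cohort.with_records(dev, label="development"),
            cohort.with_records(val, label="validation"))
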