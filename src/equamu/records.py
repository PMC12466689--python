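"""Reading, validation and consolidation of practice-management records.

A practice-management export has one row per invoiced item (a procedure, a
pharmaceutical, or some other billed service).  The analysis unit is the
*consultation*: all items for one horse at one practice on one calendar day.
This module reads delimited exports into a validated record frame,
consolidates records into consultations, and applies the study-level
inclusion filters (minimum practice size, study window).

In-memory containers are pandas DataFrames with fixed schemas:

``records``
    practice_id, horse_id, date, item_kind, anamnesis_text, diagnosis_text,
    description_text, product_id, quantity
``horses``
    practice_id, horse_id, birth_date, death_date, sex, breed
``consultations``
    practice_id, horse_id, date, n_records, combined_text (order-stable
    concatenation of the member records' free-text fields)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_KINDS",
    "RECORD_COLUMNS",
    "IngestReport",
    "StudyFilterReport",
    "read_records",
    "read_horses",
    "consolidate_consultations",
    "apply_inclusion_filters",
    "compute_age",
    "DEFAULT_WINDOW",
]

ITEM_KINDS = ("procedure", "pharmaceutical", "other")

RECORD_COLUMNS = [
    "practice_id", "horse_id", "date", "item_kind",
    "anamnesis_text", "diagnosis_text", "description_text",
    "product_id", "quantity",
]

HORSE_COLUMNS = ["practice_id", "horse_id", "birth_date", "death_date",
                 "sex", "breed"]

DEFAULT_WINDOW = (_date(2018, 1, 1), _date(2023, 12, 31))


@dataclass
class IngestReport:
    """Row-level outcome of reading an export file."""

    n_rows: int = 0
    n_valid: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.errors)


@dataclass
class StudyFilterReport:
    """What the inclusion filters removed and why."""

    min_patients: int
    window: tuple[_date, _date]
    practices_excluded: list = field(default_factory=list)
    n_records_excluded_by_date: int = 0
    n_consultations_excluded_by_practice: int = 0
    patients_per_practice: dict = field(default_factory=dict)


def _normalise_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_records(path, column_map: dict | None = None,
                 sep: str | None = None) -> tuple[pd.DataFrame, IngestReport]:
    """Read a delimited export of invoiced items into a record frame.

    ``column_map`` maps schema names to the file's header names, so real
    exports with arbitrary headers can be adapted.  Malformed rows (bad date,
    missing horse id, unknown item kind, pharmaceutical without product id)
    are excluded and counted in the returned :class:`IngestReport`, never
    silently dropped.
    """
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                      keep_default_na=False)
    raw = _normalise_columns(raw, column_map)
    missing = [c for c in ("practice_id", "horse_id", "date", "item_kind")
               if c not in raw.columns]
    if missing:
        raise ValueError(f"export is missing required columns: {missing}")
    for c in RECORD_COLUMNS:
        if c not in raw.columns:
            raw[c] = ""
    report = IngestReport(n_rows=len(raw))
    rows = []
    for idx, row in raw.iterrows():
        problems = []
        d = pd.to_datetime(row["date"], errors="coerce", format="ISO8601")
        if pd.isna(d):
            problems.append(f"unparseable date {row['date']!r}")
        if not str(row["horse_id"]).strip():
            problems.append("missing horse id")
        if not str(row["practice_id"]).strip():
            problems.append("missing practice id")
        kind = str(row["item_kind"]).strip().lower()
        if kind not in ITEM_KINDS:
            problems.append(f"unknown item kind {row['item_kind']!r}")
        product = str(row["product_id"]).strip()
        if kind == "pharmaceutical" and not product:
            problems.append("pharmaceutical item without product_id")
        if kind != "pharmaceutical" and product:
            problems.append("product_id on non-pharmaceutical item")
        qty = None
        if str(row["quantity"]).strip():
            try:
                qty = float(row["quantity"])
                if qty <= 0:
                    problems.append("non-positive quantity")
            except ValueError:
                problems.append(f"unparseable quantity {row['quantity']!r}")
        if problems:
            report.errors.append((int(idx), "; ".join(problems)))
            continue
        rows.append({
            "practice_id": str(row["practice_id"]).strip(),
            "horse_id": str(row["horse_id"]).strip(),
            "date": d.date(),
            "item_kind": kind,
            "anamnesis_text": str(row["anamnesis_text"]),
            "diagnosis_text": str(row["diagnosis_text"]),
            "description_text": str(row["description_text"]),
            "product_id": product if product else None,
            "quantity": qty,
        })
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    report.n_valid = len(records)
    return records, report


def read_horses(path, column_map: dict | None = None,
                sep: str | None = None) -> pd.DataFrame:
    """Read the patient master table (one row per horse within a practice)."""
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                      keep_default_na=False)
    raw = _normalise_columns(raw, column_map)
    for c in HORSE_COLUMNS:
        if c not in raw.columns:
            raw[c] = ""
    out = raw[HORSE_COLUMNS].copy()
    for c in ("birth_date", "death_date"):
        parsed = pd.to_datetime(out[c].replace("", pd.NA), errors="coerce",
                                format="ISO8601")
        out[c] = parsed.dt.date
    bad = out["birth_date"].notna() & out["death_date"].notna() \
        & (out["birth_date"] > out["death_date"])
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} horses have birth_date after death_date")
    return out


def consolidate_consultations(records: pd.DataFrame) -> pd.DataFrame:
    """Group same-day items of one horse into single consultation events.

    The output partitions the input: every record belongs to exactly one
    consultation keyed by (practice_id, horse_id, date), and the sum of
    ``n_records`` equals the input length.  ``combined_text`` concatenates
    each member record's anamnesis, diagnosis and description texts in input
    order (records carry no within-day times).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["practice_id", "horse_id", "date",
                                     "n_records", "combined_text"])
    df = records.copy()
    texts = (
        df["anamnesis_text"].fillna("").str.cat(
            [df["diagnosis_text"].fillna(""), df["description_text"].fillna("")],
            sep=" ")
    ).str.strip()
    df["_text"] = texts
    grouped = (
        df.groupby(["practice_id", "horse_id", "date"], sort=True)
        .agg(n_records=("_text", "size"),
             combined_text=("_text", lambda s: " ".join(t for t in s if t)))
        .reset_index()
    )
    return grouped


def apply_inclusion_filters(
    consultations: pd.DataFrame,
    min_patients: int = 100,
    window: tuple[_date, _date] = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, StudyFilterReport]:
    """Apply the study-level inclusion filters.

    Consultations outside the study window are removed first; then every
    practice with fewer than ``min_patients`` distinct horses (counted among
    in-window consultations — the only observable proxy for "registered
    patients") is removed entirely.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if window[0] > window[1]:
        raise ValueError("empty study window")
    report = StudyFilterReport(min_patients=min_patients, window=window)
    dates = pd.to_datetime(consultations["date"])
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    in_window = (dates >= lo) & (dates <= hi)
    report.n_records_excluded_by_date = int((~in_window).sum())
    kept = consultations[in_window]
    patients = kept.groupby("practice_id")["horse_id"].nunique()
    report.patients_per_practice = patients.to_dict()
    small = patients[patients < min_patients].index.tolist()
    report.practices_excluded = sorted(small)
    drop = kept["practice_id"].isin(small)
    report.n_consultations_excluded_by_practice = int(drop.sum())
    return kept[~drop].reset_index(drop=True), report


def compute_age(consultations: pd.DataFrame, horses: pd.DataFrame,
                max_plausible: float = 40.0) -> pd.DataFrame:
    """Attach ``age_years`` and ``age_plausible`` to consultations.

    Age is (consultation date - birth date) / 365.25; missing when the birth
    date is absent.  Ages outside [0, ``max_plausible``] are flagged
    implausible — they are excluded from age analyses but the consultations
    are retained everywhere else.
    """
    out = consultations.merge(
        horses[["practice_id", "horse_id", "birth_date"]],
        on=["practice_id", "horse_id"], how="left")
    d = pd.to_datetime(out["date"])
    b = pd.to_datetime(out["birth_date"])
    age = (d - b).dt.days / 365.25
    out["age_years"] = age
    out["age_plausible"] = (age >= 0) & (age <= max_plausible)
    out.loc[age.isna(), "age_plausible"] = False
    return out.drop(columns=["birth_date"])
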