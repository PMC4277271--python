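"""Cohort data model, CSV round-tripping and the admission filter.

A cohort is a set of adult acute-heart-failure admissions, each carrying an
irregularly sampled serum-creatinine (SCr) series expressed in hours relative
to admission (negative times are pre-admission draws, up to 90 days back) and
the demographic / outcome attributes needed downstream: in-hospital death or
discharge time, renal-replacement-therapy (RRT) use, and the covariates of
the adjusted mortality models.

On-disk representation is a pair of plain CSV tables (``patients.csv`` and
``measurements.csv``) sharing a ``patient_id`` key; booleans are serialized
as 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_TO_UMOL",
    "ADMISSION_SCR_EXCLUSION_UMOL",
    "DETECTION_WINDOW_HOURS",
    "MIN_STAY_HOURS",
    "PRIOR_LOOKBACK_HOURS",
    "EXCLUSION_REASONS",
    "CohortError",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "CreatinineMeasurement",
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
]

#: Conversion factor between the two creatinine conventions (1 mg/dL = 88.4 µmol/L).
MGDL_TO_UMOL = 88.4

#: Admissions at or above 3.5 mg/dL are treated as chronic, not acute, disease.
ADMISSION_SCR_EXCLUSION_UMOL = 3.5 * MGDL_TO_UMOL  # 309.4 µmol/L

#: AKI detection is restricted to the first week of the stay.
DETECTION_WINDOW_HOURS = 168.0

#: Stays (or deaths) shorter than this are considered unassessable.
MIN_STAY_HOURS = 48.0

#: Pre-admission values are usable as baseline candidates within 90 days.
PRIOR_LOOKBACK_HOURS = 2160.0


class CohortError(Exception):
    """Base class for cohort I/O and integrity problems."""


class SchemaError(CohortError):
    """A required column is missing or a table is structurally malformed."""


class IntegrityError(CohortError):
    """Cross-record constraints are violated (e.g. duplicated patient ids)."""


class ParseError(CohortError):
    """A cell could not be converted; the message names the offending rows."""


@dataclass(frozen=True)
class CreatinineMeasurement:
    """One serum-creatinine draw.

    Parameters
    ----------
    time_hours
        Hours relative to admission; negative values are pre-admission draws.
    scr_umol
        Serum creatinine in µmol/L; must be strictly positive.
    """

    time_hours: float
    scr_umol: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_hours):
            raise ValueError(f"time_hours must be finite, got {self.time_hours!r}")
        if not (math.isfinite(self.scr_umol) and self.scr_umol > 0):
            raise ValueError(f"scr_umol must be positive, got {self.scr_umol!r}")


@dataclass
class PatientRecord:
    """One hospital admission with its creatinine series and covariates."""

    patient_id: str
    age_years: float
    sex: str  # "male" | "female"
    measurements: list[CreatinineMeasurement] = field(default_factory=list)
    rrt_started: bool = False
    rrt_start_hours: Optional[float] = None
    died_in_hospital: bool = False
    outcome_time_hours: float = MIN_STAY_HOURS
    hemoglobin_g_L: Optional[float] = None
    albumin_g_L: Optional[float] = None
    acei_arb: bool = False
    diuretic: bool = False
    esrd_on_dialysis: bool = False
    malignancy: bool = False
    cardiac_surgery_aki: bool = False
    contrast_aki: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age_years < 18:
            raise ValueError(f"age_years must be >= 18, got {self.age_years}")
        if not (self.outcome_time_hours > 0):
            raise ValueError("outcome_time_hours must be positive")
        if self.rrt_started:
            if self.rrt_start_hours is None:
                raise ValueError("rrt_started requires rrt_start_hours")
            if self.rrt_start_hours > self.outcome_time_hours:
                raise ValueError("rrt_start_hours must not exceed outcome_time_hours")
        self.measurements = sorted(self.measurements, key=lambda m: m.time_hours)

    # -- series helpers -------------------------------------------------

    def series_arrays(
        self, lo: float = 0.0, hi: Optional[float] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of measurements with ``lo <= t <= hi`` (closed)."""
        t = np.array([m.time_hours for m in self.measurements], dtype=float)
        v = np.array([m.scr_umol for m in self.measurements], dtype=float)
        mask = t >= lo
        if hi is not None:
            mask &= t <= hi
        return t[mask], v[mask]

    def admission_scr(self) -> Optional[CreatinineMeasurement]:
        """First measurement at or after admission (t >= 0), if any."""
        for m in self.measurements:
            if m.time_hours >= 0:
                return m
        return None

    def prior_measurements(
        self, lookback_hours: float = PRIOR_LOOKBACK_HOURS
    ) -> list[CreatinineMeasurement]:
        """Pre-admission draws within the lookback window [-lookback, 0)."""
        return [
            m
            for m in self.measurements
            if -lookback_hours <= m.time_hours < 0
        ]


@dataclass
class Cohort:
    """A list of patients with unique ids plus free-text provenance."""

    patients: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterable[PatientRecord]:
        return iter(self.patients)

    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "rrt_started",
    "rrt_start_hours",
    "died_in_hospital",
    "outcome_time_hours",
    "hemoglobin_g_L",
    "albumin_g_L",
    "acei_arb",
    "diuretic",
    "esrd_on_dialysis",
    "malignancy",
    "cardiac_surgery_aki",
    "contrast_aki",
]

MEASUREMENT_COLUMNS = ["patient_id", "time_hours", "scr_umol"]

_BOOL_COLUMNS = [
    "rrt_started",
    "died_in_hospital",
    "acei_arb",
    "diuretic",
    "esrd_on_dialysis",
    "malignancy",
    "cardiac_surgery_aki",
    "contrast_aki",
]


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def _to_bool(series: pd.Series, name: str) -> pd.Series:
    s = pd.to_numeric(series, errors="coerce")
    bad = s.isna() | ~s.isin([0, 1])
    if bad.any():
        rows = (series.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ParseError(f"column {name!r}: expected 0/1 at csv row(s) {rows}")
    return s.astype(bool)


def _to_float(series: pd.Series, name: str, allow_na: bool = False) -> pd.Series:
    s = pd.to_numeric(series, errors="coerce")
    bad = s.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        rows = (series.index[bad] + 2).tolist()
        raise ParseError(f"column {name!r}: non-numeric value at csv row(s) {rows}")
    if not allow_na and s.isna().any():
        rows = (series.index[s.isna()] + 2).tolist()
        raise ParseError(f"column {name!r}: missing value at csv row(s) {rows}")
    return s


def read_cohort(path: str | Path, schema_version: str = "1") -> Cohort:
    """Read a cohort from ``<path>/patients.csv`` and ``<path>/measurements.csv``.

    Raises
    ------
    SchemaError
        if a required column is absent or the schema version is unknown.
    IntegrityError
        if a patient id is duplicated or a measurement references an
        unknown patient.
    ParseError
        if a numeric cell cannot be parsed (the message names the row).
    """
    if schema_version != "1":
        raise SchemaError(f"unknown schema_version {schema_version!r}")
    path = Path(path)
    ppath, mpath = path / "patients.csv", path / "measurements.csv"
    for f in (ppath, mpath):
        if not f.exists():
            raise SchemaError(f"missing cohort file: {f}")

    patients_df = pd.read_csv(
        ppath, dtype={"patient_id": str}, float_precision="round_trip"
    )
    meas_df = pd.read_csv(
        mpath, dtype={"patient_id": str}, float_precision="round_trip"
    )
    _require_columns(patients_df, PATIENT_COLUMNS, "patients.csv")
    _require_columns(meas_df, MEASUREMENT_COLUMNS, "measurements.csv")

    if patients_df["patient_id"].duplicated().any():
        dupes = sorted(patients_df.loc[patients_df["patient_id"].duplicated(), "patient_id"])
        raise IntegrityError(f"duplicate patient_id(s) in patients.csv: {dupes}")

    for col in _BOOL_COLUMNS:
        patients_df[col] = _to_bool(patients_df[col], col)
    patients_df["age_years"] = _to_float(patients_df["age_years"], "age_years")
    patients_df["outcome_time_hours"] = _to_float(
        patients_df["outcome_time_hours"], "outcome_time_hours"
    )
    for col in ("rrt_start_hours", "hemoglobin_g_L", "albumin_g_L"):
        patients_df[col] = _to_float(patients_df[col], col, allow_na=True)

    meas_df["time_hours"] = _to_float(meas_df["time_hours"], "time_hours")
    meas_df["scr_umol"] = _to_float(meas_df["scr_umol"], "scr_umol")

    known = set(patients_df["patient_id"])
    orphan = set(meas_df["patient_id"]) - known
    if orphan:
        raise IntegrityError(
            f"measurements.csv references unknown patient_id(s): {sorted(orphan)}"
        )

    by_patient: dict[str, list[CreatinineMeasurement]] = {pid: [] for pid in known}
    for row in meas_df.itertuples(index=True):
        try:
            m = CreatinineMeasurement(row.time_hours, row.scr_umol)
        except ValueError as exc:
            raise ParseError(f"measurements.csv row {row.Index + 2}: {exc}") from exc
        by_patient[row.patient_id].append(m)

    records = []
    for row in patients_df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                age_years=row.age_years,
                sex=str(row.sex),
                measurements=by_patient[row.patient_id],
                rrt_started=row.rrt_started,
                rrt_start_hours=None if pd.isna(row.rrt_start_hours) else float(row.rrt_start_hours),
                died_in_hospital=row.died_in_hospital,
                outcome_time_hours=row.outcome_time_hours,
                hemoglobin_g_L=None if pd.isna(row.hemoglobin_g_L) else float(row.hemoglobin_g_L),
                albumin_g_L=None if pd.isna(row.albumin_g_L) else float(row.albumin_g_L),
                acei_arb=row.acei_arb,
                diuretic=row.diuretic,
                esrd_on_dialysis=row.esrd_on_dialysis,
                malignancy=row.malignancy,
                cardiac_surgery_aki=row.cardiac_surgery_aki,
                contrast_aki=row.contrast_aki,
            )
        )
    return Cohort(patients=records, provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write ``patients.csv`` and ``measurements.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prow = []
    mrow = []
    for p in cohort:
        prow.append(
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "rrt_started": int(p.rrt_started),
                "rrt_start_hours": p.rrt_start_hours,
                "died_in_hospital": int(p.died_in_hospital),
                "outcome_time_hours": p.outcome_time_hours,
                "hemoglobin_g_L": p.hemoglobin_g_L,
                "albumin_g_L": p.albumin_g_L,
                "acei_arb": int(p.acei_arb),
                "diuretic": int(p.diuretic),
                "esrd_on_dialysis": int(p.esrd_on_dialysis),
                "malignancy": int(p.malignancy),
                "cardiac_surgery_aki": int(p.cardiac_surgery_aki),
                "contrast_aki": int(p.contrast_aki),
            }
        )
        for m in p.measurements:
            mrow.append(
                {"patient_id": p.patient_id, "time_hours": m.time_hours, "scr_umol": m.scr_umol}
            )
    pd.DataFrame(prow, columns=PATIENT_COLUMNS).to_csv(path / "patients.csv", index=False)
    pd.DataFrame(mrow, columns=MEASUREMENT_COLUMNS).to_csv(
        path / "measurements.csv", index=False
    )


# ---------------------------------------------------------------------------
# Admission filter
# ---------------------------------------------------------------------------

#: Fixed tally keys, in the order exclusion reasons are assigned.
EXCLUSION_REASONS = [
    "no_scr_within_window",
    "death_before_48h",
    "stay_under_48h",
    "esrd_on_dialysis",
    "admission_scr_ge_3_5_mgdl",
    "malignancy",
    "procedure_associated_aki",
]


def _exclusion_reason(p: PatientRecord, window_hours: float) -> Optional[str]:
    t, _ = p.series_arrays(0.0, window_hours)
    if t.size == 0:
        return "no_scr_within_window"
    if p.died_in_hospital and p.outcome_time_hours < MIN_STAY_HOURS:
        return "death_before_48h"
    if p.outcome_time_hours < MIN_STAY_HOURS:
        return "stay_under_48h"
    if p.esrd_on_dialysis:
        return "esrd_on_dialysis"
    admission = p.admission_scr()
    if admission is not None and admission.scr_umol >= ADMISSION_SCR_EXCLUSION_UMOL:
        return "admission_scr_ge_3_5_mgdl"
    if p.malignancy:
        return "malignancy"
    if p.cardiac_surgery_aki or p.contrast_aki:
        return "procedure_associated_aki"
    return None


def apply_exclusions(
    cohort: Cohort, window_hours: float = DETECTION_WINDOW_HOURS
) -> tuple[Cohort, dict[str, int]]:
    """Drop unassessable admissions and tally the reasons.

    Reasons are assigned by the first matching rule in :data:`EXCLUSION_REASONS`
    order, so a patient with several problems counts once and the tally plus
    the retained size always partitions the input. The operation is
    idempotent; an empty output cohort is permitted.
    """
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    kept = []
    for p in cohort:
        reason = _exclusion_reason(p, window_hours)
        if reason is None:
            kept.append(p)
        else:
            tally[reason] += 1
    retained = Cohort(patients=kept, provenance=cohort.provenance)
    return retained, tally
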