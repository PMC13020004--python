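"""Core containers for longitudinal hospitalisation data.

All dates are integer day indices relative to :data:`EPOCH` (day 0 =
2017-08-01, the opening of the emulated study window). CSV serialisation
renders them as ISO-8601 calendar dates; an empty field encodes a missing
value (e.g. no date of death).
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Calendar date of day index 0.
EPOCH = _dt.date(2017, 8, 1)

#: Columns of the patients table, in serialisation order.
PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "death_date"]

#: Columns of the stays table, in serialisation order.
STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission_date",
    "discharge_date",
    "hospital_id",
    "icd10_codes",
]

DAYS_PER_YEAR = 365.25


def day_to_iso(day: int | None) -> str:
    """Render an integer day index as an ISO-8601 date; missing -> ''."""
    if day is None or (isinstance(day, float) and np.isnan(day)):
        return ""
    return (EPOCH + _dt.timedelta(days=int(day))).isoformat()


def iso_to_day(text: str) -> float:
    """Parse an ISO-8601 date into a day index; '' -> NaN."""
    if not text:
        return float("nan")
    return float((_dt.date.fromisoformat(text) - EPOCH).days)


def stable_id_hash(identifier: str) -> int:
    """Deterministic 32-bit hash of an identifier string.

    Used to derive per-patient random streams that do not depend on how
    many other patients exist or on Python's randomised ``hash``.
    """
    return zlib.crc32(identifier.encode("utf-8"))


@dataclass
class EHRDataset:
    """A pair of patient / stay tables plus the study window.

    patients : DataFrame with columns ``patient_id`` (str), ``sex``
        ('M'/'F'), ``birth_date`` (int day index), ``death_date``
        (float day index, NaN when missing).
    stays : DataFrame with columns ``stay_id``, ``patient_id``,
        ``admission_date`` (int), ``discharge_date`` (int),
        ``hospital_id`` (int), ``icd10_codes`` (';'-separated string,
        possibly empty).
    study_window : (start_day, end_day) inclusive day indices.
    provenance : 'raw' for generated data, 'pseudonymised' after a
        date-shifting scheme has been applied.
    """

    patients: pd.DataFrame
    stays: pd.DataFrame
    study_window: tuple[int, int]
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.patients = self.patients.reset_index(drop=True)
        self.stays = self.stays.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    def copy(self) -> "EHRDataset":
        return EHRDataset(
            self.patients.copy(),
            self.stays.copy(),
            tuple(self.study_window),
            self.provenance,
        )

    def equals(self, other: "EHRDataset") -> bool:
        """Value equality of tables, window and provenance (row order included)."""
        return (
            tuple(self.study_window) == tuple(other.study_window)
            and self.provenance == other.provenance
            and self.patients[PATIENT_COLUMNS].equals(other.patients[PATIENT_COLUMNS])
            and self.stays[STAY_COLUMNS].equals(other.stays[STAY_COLUMNS])
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check structural and (for raw data) chronological invariants.

        Raises ``ValueError`` on the first violated invariant.
        Pseudonymised datasets are exempt from chronology because date
        shifting may produce spurious orderings; length of stay must
        stay non-negative in every dataset.
        """
        if self.patients["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id")
        if not set(self.stays["patient_id"]).issubset(set(self.patients["patient_id"])):
            raise ValueError("stay references unknown patient")
        los = self.stays["discharge_date"] - self.stays["admission_date"]
        if (los < 0).any():
            raise ValueError("negative length of stay")
        if self.provenance == "raw":
            merged = self.stays.merge(
                self.patients[["patient_id", "birth_date", "death_date"]],
                on="patient_id",
            )
            if (merged["admission_date"] < merged["birth_date"]).any():
                raise ValueError("admission before birth in raw dataset")
            dead = merged.dropna(subset=["death_date"])
            if (dead["discharge_date"] > dead["death_date"]).any():
                raise ValueError("discharge after death in raw dataset")
            pat = self.patients.dropna(subset=["death_date"])
            if (pat["death_date"] < pat["birth_date"]).any():
                raise ValueError("death before birth in raw dataset")

    # -- derived views ---------------------------------------------------

    def first_admissions(self) -> pd.DataFrame:
        """One row per patient: earliest stay with birth date and age (years)."""
        stays = self.stays.sort_values(["admission_date", "stay_id"], kind="stable")
        first = stays.groupby("patient_id", sort=False).first().reset_index()
        first = first.merge(self.patients[["patient_id", "birth_date", "sex"]], on="patient_id")
        first["age_years"] = (first["admission_date"] - first["birth_date"]) / DAYS_PER_YEAR
        return first


def patient_records(dataset: EHRDataset) -> dict[str, dict]:
    """Index the dataset as one plain record per patient.

    Each record holds ``sex``, ``birth`` (int), ``death`` (int or None)
    and ``stays``: a list of ``(admission, discharge, hospital)`` tuples
    sorted by (admission, discharge, hospital). This is the unit the
    attack simulation matches against.
    """
    recs: dict[str, dict] = {}
    for pid, sex, birth, death in self_iter(dataset.patients):
        recs[pid] = {
            "sex": sex,
            "birth": int(birth),
            "death": None if pd.isna(death) else int(death),
            "stays": [],
        }
    cols = ["patient_id", "admission_date", "discharge_date", "hospital_id"]
    for pid, adm, dis, hosp in dataset.stays[cols].itertuples(index=False):
        recs[pid]["stays"].append((int(adm), int(dis), int(hosp)))
    for rec in recs.values():
        rec["stays"].sort()
    return recs


def self_iter(patients: pd.DataFrame):
    return patients[PATIENT_COLUMNS].itertuples(index=False)


# -- CSV round trip ------------------------------------------------------


def write_dataset(dataset: EHRDataset, directory: str | Path) -> None:
    """Write patients.csv / stays.csv with ISO-8601 dates into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pat = dataset.patients[PATIENT_COLUMNS].copy()
    pat["birth_date"] = pat["birth_date"].map(day_to_iso)
    pat["death_date"] = pat["death_date"].map(day_to_iso)
    pat.to_csv(directory / "patients.csv", index=False)

    stays = dataset.stays[STAY_COLUMNS].copy()
    stays["admission_date"] = stays["admission_date"].map(day_to_iso)
    stays["discharge_date"] = stays["discharge_date"].map(day_to_iso)
    stays.to_csv(directory / "stays.csv", index=False)

    meta = pd.DataFrame(
        {
            "window_start": [day_to_iso(dataset.study_window[0])],
            "window_end": [day_to_iso(dataset.study_window[1])],
            "provenance": [dataset.provenance],
        }
    )
    meta.to_csv(directory / "dataset.csv", index=False)


def read_dataset(directory: str | Path) -> EHRDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    pat = pd.read_csv(directory / "patients.csv", dtype={"patient_id": str}, keep_default_na=False)
    pat["birth_date"] = pat["birth_date"].map(iso_to_day).astype(int)
    pat["death_date"] = pat["death_date"].map(iso_to_day)
    stays = pd.read_csv(
        directory / "stays.csv",
        dtype={"stay_id": str, "patient_id": str, "icd10_codes": str},
        keep_default_na=False,
    )
    stays["admission_date"] = stays["admission_date"].map(iso_to_day).astype(int)
    stays["discharge_date"] = stays["discharge_date"].map(iso_to_day).astype(int)
    stays["hospital_id"] = stays["hospital_id"].astype(int)
    meta = pd.read_csv(directory / "dataset.csv", keep_default_na=False)
    window = (
        int(iso_to_day(meta.loc[0, "window_start"])),
        int(iso_to_day(meta.loc[0, "window_end"])),
    )
    return EHRDataset(pat, stays, window, provenance=str(meta.loc[0, "provenance"]))
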