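"""Date-shifting pseudonymisation schemes.

Three schemes, in increasing order of how much per-patient temporal
coherence they destroy:

* ``base``  — every date of a patient (birth, death, all admissions and
  discharges) is shifted by one per-patient offset δt drawn uniformly on
  the closed integer interval [−Δt, +Δt]. All intra-patient intervals
  (age at admission, inter-stay gaps, time to death) are preserved.
* ``birth`` — base, plus an additional independent per-patient shift of
  the birth date drawn on [−Δt_birth, +Δt_birth], dissociating age from
  the clinical timeline.
* ``stay``  — birth, death, and each stay are shifted by independent
  offsets on [−Δt, +Δt]; admission and discharge of one stay share an
  offset so length of stay is conserved, but inter-stay gaps and event
  order are not.

Offsets are a pure function of (seed, entity id, amplitude): each entity
gets one latent uniform u from a counter-based hash, and the integer
offset is ``floor(u * (2Δ + 1)) − Δ`` — exactly uniform on {−Δ, …, +Δ},
and using common random numbers across amplitudes so that sweeping Δt
re-uses the same latent draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EHRDataset, stable_id_hash

SCHEMES = ("base", "birth", "stay")

# stream tags for the per-entity hash (distinct latent uniforms per role)
_TAG_EVENT = 1
_TAG_BIRTH_EXTRA = 2
_TAG_STAY_BIRTH = 3
_TAG_STAY_DEATH = 4
_TAG_STAY = 5


@dataclass(frozen=True)
class SchemeParams:
    """Scheme identifier plus shift amplitudes (days).

    ``delta_t_birth_max`` is only meaningful for the ``birth`` scheme and
    ignored otherwise.
    """

    scheme: str
    delta_t_max: int
    delta_t_birth_max: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.delta_t_max < 0 or self.delta_t_birth_max < 0:
            raise ValueError("amplitudes must be non-negative")


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _latent_uniform(seed: int, id_hashes: np.ndarray, tag: int) -> np.ndarray:
    """One latent uniform in [0, 1) per entity, pure in (seed, id, tag)."""
    with np.errstate(over="ignore"):
        x = (
            np.uint64(seed & 0xFFFFFFFF) << np.uint64(32)
        ) ^ id_hashes.astype(np.uint64) ^ (np.uint64(tag) * np.uint64(0xD1B54A32D192ED03))
        z = _splitmix64(x)
    return z.astype(np.float64) / float(2**64)


def _offset_from_uniform(u: np.ndarray, delta: int) -> np.ndarray:
    """Map latent uniforms to integer offsets uniform on {-delta..+delta}."""
    return (np.floor(u * (2 * delta + 1)) - delta).astype(np.int64)


def _id_hashes(ids: pd.Series) -> np.ndarray:
    return np.array([stable_id_hash(str(i)) for i in ids], dtype=np.uint64)


@dataclass
class OffsetAssignment:
    """Realised offsets for one dataset under one scheme.

    ``patient_offsets`` has one row per patient with the shift applied to
    its events (``delta_event``), its birth date (``delta_birth``, total)
    and its death date (``delta_death``). ``stay_offsets`` has one row
    per stay (``delta``); under base/birth this repeats the owning
    patient's ``delta_event``.
    """

    params: SchemeParams
    patient_offsets: pd.DataFrame
    stay_offsets: pd.DataFrame

    def within_bounds(self) -> bool:
        d, db = self.params.delta_t_max, self.params.delta_t_birth_max
        p, s = self.patient_offsets, self.stay_offsets
        birth_bound = d + db if self.params.scheme == "birth" else d
        return bool(
            p["delta_event"].abs().le(d).all()
            and p["delta_birth"].abs().le(birth_bound).all()
            and p["delta_death"].abs().le(d).all()
            and s["delta"].abs().le(d).all()
        )


def draw_offsets(dataset: EHRDataset, params: SchemeParams, seed: int) -> OffsetAssignment:
    """Draw the per-entity offsets the scheme requires.

    Per-patient (and per-stay) streams depend only on (seed, entity id),
    so adding or removing other patients never changes a patient's draw.
    """
    pids = dataset.patients["patient_id"]
    ph = _id_hashes(pids)
    d = params.delta_t_max

    delta_event = _offset_from_uniform(_latent_uniform(seed, ph, _TAG_EVENT), d)
    if params.scheme == "base":
        delta_birth = delta_event.copy()
        delta_death = delta_event.copy()
    elif params.scheme == "birth":
        extra = _offset_from_uniform(
            _latent_uniform(seed, ph, _TAG_BIRTH_EXTRA), params.delta_t_birth_max
        )
        delta_birth = delta_event + extra
        delta_death = delta_event.copy()
    else:  # stay
        delta_birth = _offset_from_uniform(_latent_uniform(seed, ph, _TAG_STAY_BIRTH), d)
        delta_death = _offset_from_uniform(_latent_uniform(seed, ph, _TAG_STAY_DEATH), d)

    patient_offsets = pd.DataFrame(
        {
            "patient_id": pids.to_numpy(),
            "delta_event": delta_event,
            "delta_birth": delta_birth,
            "delta_death": delta_death,
        }
    )

    sids = dataset.stays["stay_id"]
    if params.scheme == "stay":
        sh = _id_hashes(sids)
        stay_delta = _offset_from_uniform(_latent_uniform(seed, sh, _TAG_STAY), d)
    else:
        by_pid = dict(zip(pids, delta_event))
        stay_delta = dataset.stays["patient_id"].map(by_pid).to_numpy(dtype=np.int64)
    stay_offsets = pd.DataFrame({"stay_id": sids.to_numpy(), "delta": stay_delta})
    return OffsetAssignment(params, patient_offsets, stay_offsets)


def apply_scheme(dataset: EHRDataset, params: SchemeParams, seed: int) -> EHRDataset:
    """Return a pseudonymised copy of *dataset*; the original is untouched.

    Applying a scheme to an already-pseudonymised dataset is rejected to
    prevent accidental double shifting.
    """
    if dataset.provenance == "pseudonymised":
        raise ValueError("dataset is already pseudonymised")
    offs = draw_offsets(dataset, params, seed)

    patients = dataset.patients.copy()
    patients["birth_date"] = (
        patients["birth_date"].to_numpy() + offs.patient_offsets["delta_birth"].to_numpy()
    )
    patients["death_date"] = (
        patients["death_date"].to_numpy() + offs.patient_offsets["delta_death"].to_numpy()
    )

    stays = dataset.stays.copy()
    delta = offs.stay_offsets["delta"].to_numpy()
    stays["admission_date"] = stays["admission_date"].to_numpy() + delta
    stays["discharge_date"] = stays["discharge_date"].to_numpy() + delta

    return EHRDataset(patients, stays, tuple(dataset.study_window), provenance="pseudonymised")


def verify_scheme_properties(
    raw: EHRDataset, pseudo: EHRDataset, params: SchemeParams
) -> dict:
    """Check that *pseudo* is a legal image of *raw* under *params*.

    Returns ``{"passed": bool, "failures": [records]}`` where each
    failure record names the entity and the violated property: length of
    stay conservation, shared per-patient offsets (base/birth), and all
    offsets within their configured bounds.
    """
    failures: list[dict] = []
    d, db = params.delta_t_max, params.delta_t_birth_max

    pat = raw.patients.merge(
        pseudo.patients, on="patient_id", suffixes=("_raw", "_pse")
    )
    stays = raw.stays.merge(pseudo.stays, on="stay_id", suffixes=("_raw", "_pse"))

    los_raw = stays["discharge_date_raw"] - stays["admission_date_raw"]
    los_pse = stays["discharge_date_pse"] - stays["admission_date_pse"]
    for sid in stays.loc[los_raw.ne(los_pse), "stay_id"]:
        failures.append({"entity": sid, "property": "length_of_stay_conserved"})

    stays["shift"] = stays["admission_date_pse"] - stays["admission_date_raw"]
    for sid in stays.loc[stays["shift"].abs() > d, "stay_id"]:
        failures.append({"entity": sid, "property": "stay_shift_in_range"})

    birth_shift = pat["birth_date_pse"] - pat["birth_date_raw"]
    death_shift = pat["death_date_pse"] - pat["death_date_raw"]
    birth_bound = d + db if params.scheme == "birth" else d
    for pid in pat.loc[birth_shift.abs() > birth_bound, "patient_id"]:
        failures.append({"entity": pid, "property": "birth_shift_in_range"})
    for pid in pat.loc[death_shift.abs() > d, "patient_id"]:
        failures.append({"entity": pid, "property": "death_shift_in_range"})

    if params.scheme in ("base", "birth"):
        per_pat = stays.groupby("patient_id_raw")["shift"].nunique()
        for pid in per_pat.index[per_pat > 1]:
            failures.append({"entity": pid, "property": "single_offset_per_patient"})
        stay_shift = stays.groupby("patient_id_raw")["shift"].first()
        joined = pat.set_index("patient_id").join(stay_shift.rename("stay_shift"), how="inner")
        bad_death = joined.index[
            (joined["death_date_pse"] - joined["death_date_raw"]).sub(joined["stay_shift"]).abs()
            > 0
        ]
        for pid in bad_death:
            failures.append({"entity": pid, "property": "death_shares_event_offset"})
        if params.scheme == "base":
            bad_birth = joined.index[
                (joined["birth_date_pse"] - joined["birth_date_raw"]) != joined["stay_shift"]
            ]
            for pid in bad_birth:
                failures.append({"entity": pid, "property": "birth_shares_event_offset"})
        else:
            extra = (
                joined["birth_date_pse"] - joined["birth_date_raw"] - joined["stay_shift"]
            )
            for pid in joined.index[extra.abs() > db]:
                failures.append({"entity": pid, "property": "birth_extra_shift_in_range"})

    return {"passed": not failures, "failures": failures}
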