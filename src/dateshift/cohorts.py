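"""Cohort definition and data minimisation.

A cohort is the set of patients a study (and hence an attacker with
legitimate access) gets to see. Minimisation here means restricting
cohort membership — by ICD-10 inclusion criteria, admission window, age
window, and optional random subsampling — which drives the attacker's
probability of even holding the target's record, P(access) =
n_cohort / n_total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DAYS_PER_YEAR, EHRDataset


@dataclass(frozen=True)
class CohortCriteria:
    """Patient-level inclusion criteria.

    A patient is included if at least one stay matches *all* criteria:
    any of its ICD-10 codes starts with one of ``icd10_prefixes`` (the
    empty prefix matches every stay), the admission lies inside
    ``admission_window``, and the age at that admission lies inside
    ``age_window`` (years). ``sample_fraction`` keeps each included
    patient with that probability (Bernoulli, seeded).
    """

    icd10_prefixes: tuple[str, ...] = ("",)
    admission_window: tuple[int, int] | None = None
    age_window: tuple[float, float] | None = None
    sample_fraction: float | None = None
    sample_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_fraction is not None and not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")
        for window in (self.admission_window, self.age_window):
            if window is not None and window[0] > window[1]:
                raise ValueError("window bounds must be ordered")


@dataclass(frozen=True)
class Cohort:
    criteria: CohortCriteria
    patient_ids: frozenset[str]
    n_total: int

    @property
    def n_cohort(self) -> int:
        return len(self.patient_ids)


def _stay_matches(dataset: EHRDataset, criteria: CohortCriteria) -> pd.Series:
    stays = dataset.stays
    codes = stays["icd10_codes"].fillna("")
    mask = pd.Series(False, index=stays.index)
    for prefix in criteria.icd10_prefixes:
        if prefix == "":
            mask |= True
        else:
            mask |= codes.map(
                lambda s, p=prefix: any(c.startswith(p) for c in s.split(";") if c)
            )
    if criteria.admission_window is not None:
        lo, hi = criteria.admission_window
        mask &= stays["admission_date"].between(lo, hi)
    if criteria.age_window is not None:
        lo, hi = criteria.age_window
        birth = stays["patient_id"].map(
            dict(zip(dataset.patients["patient_id"], dataset.patients["birth_date"]))
        )
        age = (stays["admission_date"] - birth) / DAYS_PER_YEAR
        mask &= age.between(lo, hi)
    return mask


def build_cohort(dataset: EHRDataset, criteria: CohortCriteria) -> Cohort:
    """Patients with at least one stay matching all criteria.

    Criteria are evaluated on the dataset as given — on pseudonymised
    dates if the dataset is pseudonymised, which is what makes events
    shifted outside a study window drop out of its cohort.
    """
    matched = dataset.stays.loc[_stay_matches(dataset, criteria), "patient_id"]
    ids = sorted(set(matched))
    if criteria.sample_fraction is not None and criteria.sample_fraction < 1.0:
        rng = np.random.default_rng(criteria.sample_seed)
        keep = rng.random(len(ids)) < criteria.sample_fraction
        ids = [pid for pid, k in zip(ids, keep) if k]
    return Cohort(criteria, frozenset(ids), n_total=dataset.n_patients)


def p_access(cohort: Cohort, target_in_cohort: bool = False) -> float:
    """Probability that the attacker's accessed cohort holds the target.

    ``n_cohort / n_total`` for a randomly chosen target; exactly 1 when
    the attacker knows the target is in the cohort.
    """
    if target_in_cohort:
        return 1.0
    if cohort.n_total == 0:
        raise ValueError("n_total must be positive")
    return cohort.n_cohort / cohort.n_total
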