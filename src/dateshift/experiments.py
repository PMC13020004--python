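"""End-to-end experiment orchestration.

Runs the full pipeline — generate, pseudonymise over a scheme x
amplitude grid, attack under both scenarios, re-run the six studies —
and assembles the privacy-utility trade-off table: one row per
(study, scheme, Δt, scenario) with uniqueness, P(access), P(success)
and the study's unreliability score.

Amplitude grids share one latent offset draw (common random numbers):
sweeping Δt re-scales the same per-patient uniforms, so uniqueness
comparisons along the grid are paired rather than independently noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attacks import (
    FULL_KNOWLEDGE,
    AttackerKnowledge,
    SearchIndex,
    UniquenessReport,
    restrict,
)
from .cohorts import Cohort, CohortCriteria, build_cohort, p_access
from .core import EHRDataset, patient_records, stable_id_hash
from .schemes import SchemeParams, apply_scheme
from .studies import (
    StudyResult,
    study_bariatric,
    study_care_pathways,
    study_epidemic,
    study_hosp_characterisation,
    study_survival,
    unreliability,
)
from .synthetic import SyntheticConfig, generate_full_dataset

#: study name -> ICD-10 prefix defining its cohort ('' = all patients)
DEFAULT_STUDY_COHORTS = {
    "hosp_characterisation": "",
    "bronchiolitis": "J21",
    "flu": "J10",
    "bariatric": "K95",
    "pancreatic_survival": "C25",
    "care_pathways": "C25",
}

DEFAULT_DELTA_GRID = (0, 7, 10, 30, 100, 1000)


@dataclass
class ExperimentPlan:
    """Everything needed to reproduce one full trade-off experiment."""

    config: SyntheticConfig = field(default_factory=SyntheticConfig)
    schemes: tuple[str, ...] = ("base", "birth", "stay")
    delta_grid: tuple[int, ...] = DEFAULT_DELTA_GRID
    birth_delta_equals_event: bool = True  # birth scheme: Δt_birth = Δt
    study_cohorts: dict = field(default_factory=lambda: dict(DEFAULT_STUDY_COHORTS))
    scenarios: tuple[str, ...] = ("random_target", "target_in_cohort")
    knowledge: frozenset = FULL_KNOWLEDGE
    target_sample: int = 500
    master_seed: int = 0
    window_filter: bool = True


def cell_seed(master_seed: int, *coords) -> int:
    """Deterministic sub-seed below 2**31 for one grid cell."""
    return stable_id_hash(f"{master_seed}:" + ":".join(map(str, coords))) & 0x7FFFFFFF


def _run_study(name: str, dataset: EHRDataset, plan: ExperimentPlan) -> StudyResult:
    prefix = plan.study_cohorts[name]
    if name == "hosp_characterisation":
        return study_hosp_characterisation(dataset)
    if name in ("bronchiolitis", "flu"):
        return study_epidemic(dataset, prefix, week_origin=dataset.study_window[0])
    if name == "bariatric":
        return study_bariatric(dataset, marker_prefix=prefix)
    if name == "pancreatic_survival":
        return study_survival(dataset, code_prefix=prefix, window_filter=plan.window_filter)
    if name == "care_pathways":
        return study_care_pathways(dataset, code_prefix=prefix, seed=plan.master_seed)
    raise ValueError(f"unknown study {name!r}")


def _sample_targets(ids: list[str], n: int, seed: int) -> list[str]:
    ids = sorted(ids)
    if n >= len(ids):
        return ids
    rng = np.random.default_rng(seed)
    return list(rng.choice(np.array(ids), n, replace=False))


def _uniqueness_from_records(
    true_records: dict,
    search_records: dict,
    targets: list[str],
    known: frozenset,
    params: SchemeParams,
) -> UniquenessReport:
    index = SearchIndex(search_records, known, params)
    per_k = {
        pid: index.k_anonymity(AttackerKnowledge(known, true_records[pid]))
        for pid in targets
    }
    return UniquenessReport(per_k)


def run_experiment(plan: ExperimentPlan, dataset: EHRDataset | None = None) -> pd.DataFrame:
    """Execute every grid cell of *plan* and return the trade-off table.

    A failed cell is recorded with its error in the ``flags`` column and
    the run continues.
    """
    if dataset is None:
        dataset = generate_full_dataset(plan.config)
    true_records = patient_records(dataset)
    originals = {name: _run_study(name, dataset, plan) for name in plan.study_cohorts}
    cohorts_raw = {
        name: build_cohort(dataset, CohortCriteria(icd10_prefixes=(prefix,)))
        for name, prefix in plan.study_cohorts.items()
    }

    rows = []
    for scheme in plan.schemes:
        for dt in plan.delta_grid:
            dtb = dt if (scheme == "birth" and plan.birth_delta_equals_event) else 0
            params = SchemeParams(scheme, dt, dtb)
            pseudo = apply_scheme(dataset, params, plan.master_seed)
            pseudo_records = patient_records(pseudo)

            unrel = {}
            for name in plan.study_cohorts:
                try:
                    result = _run_study(name, pseudo, plan)
                    unrel[name] = (unreliability(originals[name], result), "")
                except Exception as exc:  # noqa: BLE001 - cell failure is recorded
                    unrel[name] = (None, f"study_failed: {exc}")

            for name, cohort in cohorts_raw.items():
                targets = _sample_targets(
                    list(cohort.patient_ids), plan.target_sample, plan.master_seed
                )
                score, flag = unrel[name]
                for scenario in plan.scenarios:
                    if not targets:
                        rows.append(
                            {
                                "study": name,
                                "scheme": scheme,
                                "delta_t": dt,
                                "delta_t_birth": dtb,
                                "scenario": scenario,
                                "n_cohort": 0,
                                "n_total": dataset.n_patients,
                                "p_access": 0.0,
                                "uniqueness": float("nan"),
                                "p_success": float("nan"),
                                "unreliability": score.value if score else float("nan"),
                                "flags": flag or "empty_cohort",
                            }
                        )
                        continue
                    if scenario == "random_target":
                        search = pseudo_records
                        access = p_access(cohort)
                    else:
                        search = {pid: pseudo_records[pid] for pid in cohort.patient_ids}
                        access = 1.0
                    report = _uniqueness_from_records(
                        true_records, search, targets, plan.knowledge, params
                    )
                    rows.append(
                        {
                            "study": name,
                            "scheme": scheme,
                            "delta_t": dt,
                            "delta_t_birth": dtb,
                            "scenario": scenario,
                            "n_cohort": cohort.n_cohort,
                            "n_total": dataset.n_patients,
                            "p_access": access,
                            "uniqueness": report.uniqueness,
                            "p_success": access * report.uniqueness,
                            "unreliability": score.value if score else float("nan"),
                            "flags": flag,
                        }
                    )
    return pd.DataFrame(rows)


def uniqueness_grid(
    dataset: EHRDataset,
    schemes: tuple[str, ...],
    delta_grid: tuple[int, ...],
    known: frozenset = FULL_KNOWLEDGE,
    seed: int = 0,
    target_sample: int = 500,
    birth_delta_equals_event: bool = True,
) -> pd.DataFrame:
    """Uniqueness of sampled targets in the total dataset per (scheme, Δt)."""
    true_records = patient_records(dataset)
    targets = _sample_targets(list(true_records), target_sample, seed)
    rows = []
    for scheme in schemes:
        for dt in delta_grid:
            dtb = dt if (scheme == "birth" and birth_delta_equals_event) else 0
            params = SchemeParams(scheme, dt, dtb)
            pseudo = apply_scheme(dataset, params, seed)
            report = _uniqueness_from_records(
                true_records, patient_records(pseudo), targets, known, params
            )
            rows.append(
                {
                    "scheme": scheme,
                    "delta_t": dt,
                    "delta_t_birth": dtb,
                    "uniqueness": report.uniqueness,
                }
            )
    return pd.DataFrame(rows)


def birth_param_sweep(
    dataset: EHRDataset,
    delta_grid: tuple[int, ...] = DEFAULT_DELTA_GRID,
    delta_birth_grid: tuple[int, ...] | None = None,
    known: frozenset = FULL_KNOWLEDGE,
    seed: int = 0,
    target_sample: int = 500,
) -> pd.DataFrame:
    """Uniqueness over the (Δt, Δt_birth) grid of the birth scheme.

    Returns a matrix indexed by Δt (rows) x Δt_birth (columns); marginal
    slices are its first row and first column.
    """
    if delta_birth_grid is None:
        delta_birth_grid = delta_grid
    true_records = patient_records(dataset)
    targets = _sample_targets(list(true_records), target_sample, seed)
    matrix = pd.DataFrame(index=list(delta_grid), columns=list(delta_birth_grid), dtype=float)
    for dt in delta_grid:
        for dtb in delta_birth_grid:
            params = SchemeParams("birth", dt, dtb)
            pseudo = apply_scheme(dataset, params, seed)
            report = _uniqueness_from_records(
                true_records, patient_records(pseudo), targets, known, params
            )
            matrix.loc[dt, dtb] = report.uniqueness
    matrix.index.name = "delta_t"
    matrix.columns.name = "delta_t_birth"
    return matrix
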