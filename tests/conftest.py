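"""Shared fixtures and record-fuzzing helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dateshift import (
    EHRDataset,
    SchemeParams,
    SyntheticConfig,
    generate_full_dataset,
    generate_population,
)

PATIENT_COLS = ["patient_id", "sex", "birth_date", "death_date"]
STAY_COLS = [
    "stay_id",
    "patient_id",
    "admission_date",
    "discharge_date",
    "hospital_id",
    "icd10_codes",
]


def make_dataset(patients, stays, window=(0, 2435), provenance="raw") -> EHRDataset:
    """Build a dataset from plain tuples (see column lists above)."""
    pat = pd.DataFrame(patients, columns=PATIENT_COLS)
    pat["death_date"] = pat["death_date"].astype(float)
    st = pd.DataFrame(stays, columns=STAY_COLS)
    return EHRDataset(pat, st, window, provenance=provenance)


@pytest.fixture(scope="session")
def pop_small() -> EHRDataset:
    """Background population, 400 patients."""
    return generate_population(SyntheticConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def full_small() -> EHRDataset:
    """Full synthetic dataset (epidemics + cohorts), ~2000 background patients."""
    return generate_full_dataset(SyntheticConfig(n_patients=2000, seed=21))


# -- record fuzzing for matcher/oracle equivalence -----------------------


def random_record(rng: np.random.Generator, n_stays: int | None = None) -> dict:
    n = n_stays if n_stays is not None else int(rng.integers(1, 4))
    stays = []
    for _ in range(n):
        adm = int(rng.integers(0, 200))
        los = int(rng.integers(0, 6))
        stays.append((adm, adm + los, int(rng.integers(1, 4))))
    death = int(rng.integers(100, 400)) if rng.random() < 0.3 else None
    return {
        "sex": "M" if rng.random() < 0.5 else "F",
        "birth": int(rng.integers(-20000, 0)),
        "death": death,
        "stays": sorted(stays),
    }


def perturb_record(rng: np.random.Generator, rec: dict, scale: int) -> dict:
    """Randomly nudge one attribute — produces near-miss candidates."""
    r = {
        "sex": rec["sex"],
        "birth": rec["birth"],
        "death": rec["death"],
        "stays": [list(s) for s in rec["stays"]],
    }
    mode = rng.integers(0, 6)
    if mode == 0 and r["stays"]:
        i = rng.integers(0, len(r["stays"]))
        d = int(rng.integers(-scale, scale + 1))
        r["stays"][i][0] += d
        r["stays"][i][1] += d
    elif mode == 1 and r["stays"]:
        i = rng.integers(0, len(r["stays"]))
        r["stays"][i][1] += int(rng.integers(0, 3))
    elif mode == 2:
        r["birth"] += int(rng.integers(-scale, scale + 1))
    elif mode == 3 and r["death"] is not None:
        r["death"] += int(rng.integers(-scale, scale + 1))
    elif mode == 4 and r["stays"]:
        i = rng.integers(0, len(r["stays"]))
        r["stays"][i][2] = int(rng.integers(1, 4))
    else:
        r["sex"] = "M" if r["sex"] == "F" else "F"
    r["stays"] = sorted(tuple(s) for s in r["stays"])
    return r


def legal_pseudonymisation(rng: np.random.Generator, rec: dict, params: SchemeParams) -> dict:
    """A candidate produced by a legal random offset assignment."""
    d, db = params.delta_t_max, params.delta_t_birth_max
    out = {"sex": rec["sex"], "stays": [], "birth": 0, "death": None}
    if params.scheme in ("base", "birth"):
        delta = int(rng.integers(-d, d + 1))
        out["stays"] = sorted((a + delta, di + delta, h) for a, di, h in rec["stays"])
        extra = int(rng.integers(-db, db + 1)) if params.scheme == "birth" else 0
        out["birth"] = rec["birth"] + delta + extra
        out["death"] = None if rec["death"] is None else rec["death"] + delta
    else:
        shifted = []
        for a, di, h in rec["stays"]:
            delta = int(rng.integers(-d, d + 1))
            shifted.append((a + delta, di + delta, h))
        out["stays"] = sorted(shifted)
        out["birth"] = rec["birth"] + int(rng.integers(-d, d + 1))
        out["death"] = (
            None if rec["death"] is None else rec["death"] + int(rng.integers(-d, d + 1))
        )
    return out


def fuzz_pairs(rng: np.random.Generator, params: SchemeParams, n: int):
    """Yield (target, candidate) mixing legal images, near misses, randoms."""
    for trial in range(n):
        target = random_record(rng)
        mode = trial % 3
        if mode == 0:
            cand = legal_pseudonymisation(rng, target, params)
        elif mode == 1:
            cand = legal_pseudonymisation(
                rng, perturb_record(rng, target, max(params.delta_t_max, 3)), params
            )
        else:
            cand = random_record(rng)
        yield target, cand
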