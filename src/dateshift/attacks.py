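"""Re-identification attack simulation on date-shifted records.

The attacker holds the *true* (pre-pseudonymisation) values of some
attributes of a target — sex, birth date, stay dates, hospitals visited,
death date — and knows the pseudonymisation scheme and its amplitudes
(Kerckhoffs' principle), but not the realised random offsets. A
pseudonymised candidate record is *compatible* with the target when some
offset assignment that is legal under the scheme maps the target's true
values exactly onto the candidate.

The equivalence-class size k of a target is the number of compatible
records in the searched set; uniqueness is the fraction of targets with
k = 1, and the success probability of an attack is
P(success) = P(access) x P(unique | cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .cohorts import Cohort, p_access
from .core import DAYS_PER_YEAR, EHRDataset, patient_records
from .schemes import SchemeParams

#: All quasi-identifier attributes the attacker may know.
ATTRIBUTES = ("sex", "birth_date", "stay_dates", "hospitals", "death_date")
FULL_KNOWLEDGE = frozenset(ATTRIBUTES)

#: Nested knowledge subsets used for the ablation, weakest to strongest.
NESTED_SUBSETS = (
    frozenset({"sex"}),
    frozenset({"sex", "hospitals"}),
    frozenset({"sex", "hospitals", "birth_date"}),
    frozenset({"sex", "hospitals", "birth_date", "death_date"}),
    FULL_KNOWLEDGE,
)

_BRUTEFORCE_DELTA_BOUND = 200


@dataclass(frozen=True)
class AttackerKnowledge:
    """The attacked attributes and the target's true record.

    ``target`` is a plain record: ``sex``, ``birth`` (day), ``death``
    (day or None), ``stays`` — list of (admission, discharge, hospital).
    """

    known: frozenset
    target: dict

    def __post_init__(self) -> None:
        if not self.known:
            raise ValueError("attacker must know at least one attribute")
        unknown = self.known - set(ATTRIBUTES)
        if unknown:
            raise ValueError(f"unknown attributes {sorted(unknown)}")


# -- single-candidate compatibility --------------------------------------


def _hospital_multiset_ok(target: dict, candidate: dict, as_set: bool) -> bool:
    th = [s[2] for s in target["stays"]]
    ch = [s[2] for s in candidate["stays"]]
    if as_set:
        return set(th) == set(ch)
    return sorted(th) == sorted(ch)


def _stay_matching_exists(
    t_stays: list, c_stays: list, delta: int, match_hospital: bool
) -> bool:
    """Perfect matching between true and candidate stays (stay scheme).

    A pair is admissible when lengths of stay are equal, hospitals are
    equal (if known) and the implied admission offset lies in
    [-delta, +delta]. Kuhn's augmenting-path algorithm; stay counts are
    small so the O(V.E) bound is irrelevant.
    """
    n = len(t_stays)
    adj: list[list[int]] = []
    for adm, dis, hosp in t_stays:
        row = [
            j
            for j, (cadm, cdis, chosp) in enumerate(c_stays)
            if cdis - cadm == dis - adm
            and abs(cadm - adm) <= delta
            and (not match_hospital or chosp == hosp)
        ]
        if not row:
            return False
        adj.append(row)

    match_of_candidate = [-1] * n

    def try_augment(i: int, visited: list[bool]) -> bool:
        for j in adj[i]:
            if not visited[j]:
                visited[j] = True
                if match_of_candidate[j] == -1 or try_augment(match_of_candidate[j], visited):
                    match_of_candidate[j] = i
                    return True
        return False

    for i in range(n):
        if not try_augment(i, [False] * n):
            return False
    return True


def compatible(
    knowledge: AttackerKnowledge,
    candidate: dict,
    params: SchemeParams,
    hospitals_as_set: bool = False,
) -> bool:
    """Could *candidate* be the target's pseudonymised record?

    True iff there exists an offset assignment legal under *params*
    mapping the target's known true attributes exactly onto the
    candidate's values.
    """
    known, t = knowledge.known, knowledge.target
    d = params.delta_t_max
    db = params.delta_t_birth_max if params.scheme == "birth" else 0

    if "sex" in known and candidate["sex"] != t["sex"]:
        return False
    if "death_date" in known:
        if (t["death"] is None) != (candidate["death"] is None):
            return False

    if params.scheme in ("base", "birth"):
        points: list[int] = []  # offsets forced exactly
        interval = [-d, d]  # feasible range for the shared event offset

        if "stay_dates" in known:
            ts, cs = t["stays"], candidate["stays"]
            if len(ts) != len(cs):
                return False
            if "hospitals" in known and not hospitals_as_set:
                key = lambda s: (s[0], s[1], s[2])
            else:
                key = lambda s: (s[0], s[1])
            ts, cs = sorted(ts, key=key), sorted(cs, key=key)
            if "hospitals" in known and hospitals_as_set:
                if not _hospital_multiset_ok(t, candidate, as_set=True):
                    return False
            for (adm, dis, hosp), (cadm, cdis, chosp) in zip(ts, cs):
                if cdis - cadm != dis - adm:
                    return False
                if "hospitals" in known and not hospitals_as_set and chosp != hosp:
                    return False
                points.append(cadm - adm)
        elif "hospitals" in known:
            if not _hospital_multiset_ok(t, candidate, as_set=hospitals_as_set):
                return False

        if "death_date" in known and t["death"] is not None:
            points.append(candidate["death"] - t["death"])
        if "birth_date" in known:
            b = candidate["birth"] - t["birth"]
            if params.scheme == "base":
                points.append(b)
            else:
                interval[0] = max(interval[0], b - db)
                interval[1] = min(interval[1], b + db)

        if points:
            delta0 = points[0]
            return (
                all(p == delta0 for p in points)
                and interval[0] <= delta0 <= interval[1]
            )
        return interval[0] <= interval[1]

    # stay scheme: independent offsets for birth, death and each stay
    if "birth_date" in known and abs(candidate["birth"] - t["birth"]) > d:
        return False
    if (
        "death_date" in known
        and t["death"] is not None
        and abs(candidate["death"] - t["death"]) > d
    ):
        return False
    if "stay_dates" in known:
        ts, cs = t["stays"], candidate["stays"]
        if len(ts) != len(cs):
            return False
        if "hospitals" in known and hospitals_as_set:
            if not _hospital_multiset_ok(t, candidate, as_set=True):
                return False
        return _stay_matching_exists(
            ts, cs, d, match_hospital="hospitals" in known and not hospitals_as_set
        )
    if "hospitals" in known:
        return _hospital_multiset_ok(t, candidate, as_set=hospitals_as_set)
    return True


def compatible_bruteforce(
    knowledge: AttackerKnowledge,
    candidate: dict,
    params: SchemeParams,
    hospitals_as_set: bool = False,
) -> bool:
    """Same contract as :func:`compatible`, by exhaustive enumeration.

    Enumerates every integer offset assignment (and, for the stay
    scheme, every pairing of true to candidate stays). Only feasible for
    small amplitudes; serves as the independent oracle in tests.
    """
    d = params.delta_t_max
    db = params.delta_t_birth_max if params.scheme == "birth" else 0
    if max(d, db) > _BRUTEFORCE_DELTA_BOUND:
        raise ValueError("amplitude too large for brute-force enumeration")
    known, t = knowledge.known, knowledge.target

    if "sex" in known and candidate["sex"] != t["sex"]:
        return False
    if "death_date" in known and (t["death"] is None) != (candidate["death"] is None):
        return False
    if "hospitals" in known and not _hospital_multiset_ok(
        t, candidate, as_set=hospitals_as_set
    ):
        if "stay_dates" not in known or hospitals_as_set:
            return False

    def stays_map_exactly(delta: int) -> bool:
        shifted = sorted((a + delta, di + delta, h) for a, di, h in t["stays"])
        if "hospitals" in known and not hospitals_as_set:
            return shifted == sorted(candidate["stays"])
        return sorted((a, di) for a, di, _ in shifted) == sorted(
            (a, di) for a, di, _ in candidate["stays"]
        )

    if params.scheme in ("base", "birth"):
        for delta in range(-d, d + 1):
            if "stay_dates" in known:
                if len(t["stays"]) != len(candidate["stays"]):
                    return False
                if not stays_map_exactly(delta):
                    continue
            if "death_date" in known and t["death"] is not None:
                if candidate["death"] != t["death"] + delta:
                    continue
            if "birth_date" in known:
                if params.scheme == "base":
                    if candidate["birth"] != t["birth"] + delta:
                        continue
                else:
                    if not any(
                        t["birth"] + delta + eb == candidate["birth"]
                        for eb in range(-db, db + 1)
                    ):
                        continue
            return True
        return False

    # stay scheme
    if "birth_date" in known and not any(
        t["birth"] + delta == candidate["birth"] for delta in range(-d, d + 1)
    ):
        return False
    if "death_date" in known and t["death"] is not None:
        if not any(
            t["death"] + delta == candidate["death"] for delta in range(-d, d + 1)
        ):
            return False
    if "stay_dates" in known:
        ts, cs = t["stays"], candidate["stays"]
        if len(ts) != len(cs):
            return False
        for perm in permutations(range(len(cs))):
            ok = True
            for i, (adm, dis, hosp) in enumerate(ts):
                cadm, cdis, chosp = cs[perm[i]]
                if cdis - cadm != dis - adm or abs(cadm - adm) > d:
                    ok = False
                    break
                if "hospitals" in known and not hospitals_as_set and chosp != hosp:
                    ok = False
                    break
            if ok:
                return True
        return False
    return True


# -- search index with lossless blocking ---------------------------------


class SearchIndex:
    """Pre-indexed pseudonymised records for fast k-anonymity queries.

    Candidates are blocked on the attributes that every scheme preserves
    exactly — sex, death presence, stay count, the multiset of lengths
    of stay and (when known) of hospitals — and pre-filtered on the
    earliest admission, whose shift is bounded by the amplitude under
    every scheme. Blocking is therefore lossless: it never discards a
    compatible candidate.
    """

    def __init__(
        self,
        records: dict[str, dict],
        known: frozenset,
        params: SchemeParams,
        hospitals_as_set: bool = False,
    ):
        self.known = known
        self.params = params
        self.hospitals_as_set = hospitals_as_set
        self.records = records
        self._blocks: dict[tuple, list[tuple[str, dict, int]]] = {}
        for pid, rec in records.items():
            key = self._block_key(rec)
            min_adm = min((s[0] for s in rec["stays"]), default=0)
            self._blocks.setdefault(key, []).append((pid, rec, min_adm))

    def _block_key(self, rec: dict) -> tuple:
        parts: list = []
        if "sex" in self.known:
            parts.append(rec["sex"])
        if "death_date" in self.known:
            parts.append(rec["death"] is None)
        if "stay_dates" in self.known:
            parts.append(len(rec["stays"]))
            parts.append(tuple(sorted(dis - adm for adm, dis, _ in rec["stays"])))
        if "hospitals" in self.known:
            hs = [h for _, _, h in rec["stays"]]
            parts.append(
                tuple(sorted(set(hs))) if self.hospitals_as_set else tuple(sorted(hs))
            )
        return tuple(parts)

    def k_anonymity(self, knowledge: AttackerKnowledge) -> int:
        """Number of indexed records compatible with the target."""
        t = knowledge.target
        block = self._blocks.get(self._block_key(t), [])
        if not block:
            return 0
        d = self.params.delta_t_max
        db = self.params.delta_t_birth_max if self.params.scheme == "birth" else 0
        t_min_adm = min((s[0] for s in t["stays"]), default=0)
        k = 0
        for _, rec, min_adm in block:
            if "stay_dates" in self.known and abs(min_adm - t_min_adm) > d:
                continue
            if "birth_date" in self.known and abs(rec["birth"] - t["birth"]) > d + db:
                continue
            if compatible(knowledge, rec, self.params, self.hospitals_as_set):
                k += 1
        return k


def k_anonymity(
    knowledge: AttackerKnowledge,
    search_set: EHRDataset | dict,
    params: SchemeParams,
    hospitals_as_set: bool = False,
) -> int:
    """Equivalence-class size of the target within *search_set*."""
    records = search_set if isinstance(search_set, dict) else patient_records(search_set)
    index = SearchIndex(records, knowledge.known, params, hospitals_as_set)
    return index.k_anonymity(knowledge)


# -- uniqueness reports --------------------------------------------------


@dataclass
class UniquenessReport:
    """Per-target k, uniqueness and the k-anonymity histogram."""

    per_record_k: dict[str, int]
    scenario: str | None = None
    p_access_value: float | None = None

    @property
    def uniqueness(self) -> float:
        if not self.per_record_k:
            return float("nan")
        ks = np.fromiter(self.per_record_k.values(), dtype=int)
        return float((ks == 1).mean())

    @property
    def k_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for k in self.per_record_k.values():
            hist[k] = hist.get(k, 0) + 1
        return dict(sorted(hist.items()))

    @property
    def p_success(self) -> float | None:
        if self.p_access_value is None:
            return None
        return self.p_access_value * self.uniqueness


def uniqueness(
    raw: EHRDataset,
    pseudo: EHRDataset,
    known: frozenset,
    params: SchemeParams,
    target_ids: list[str] | None = None,
    sample_size: int | None = None,
    sample_seed: int = 0,
    hospitals_as_set: bool = False,
) -> UniquenessReport:
    """Uniqueness of *targets* (true records from *raw*) in *pseudo*.

    For the random-target scenario *pseudo* is the whole pseudonymised
    dataset; for target-in-cohort it is the accessed cohort's records
    and the targets are the cohort members. Large target sets can be
    subsampled (``sample_size``, seeded) — the estimate is then a
    Monte-Carlo one over targets, the search remains exhaustive.
    """
    true_records = patient_records(raw)
    search_records = patient_records(pseudo)
    if target_ids is None:
        target_ids = sorted(search_records)
    if not target_ids:
        raise ValueError("empty target set")
    if sample_size is not None and sample_size < len(target_ids):
        rng = np.random.default_rng(sample_seed)
        target_ids = list(rng.choice(np.array(sorted(target_ids)), sample_size, replace=False))
    index = SearchIndex(search_records, known, params, hospitals_as_set)
    per_k = {
        pid: index.k_anonymity(AttackerKnowledge(known, true_records[pid]))
        for pid in target_ids
    }
    return UniquenessReport(per_k)


def exact_match_uniqueness(dataset: EHRDataset, known: frozenset) -> float:
    """Fraction of records unique on exact equality of known attributes.

    This is what uniqueness degenerates to at zero shift amplitude.
    """
    records = patient_records(dataset)
    keys: dict[tuple, int] = {}
    sigs = {}
    for pid, rec in records.items():
        parts: list = []
        if "sex" in known:
            parts.append(rec["sex"])
        if "birth_date" in known:
            parts.append(rec["birth"])
        if "death_date" in known:
            parts.append(rec["death"])
        if "stay_dates" in known:
            if "hospitals" in known:
                parts.append(tuple(sorted(rec["stays"])))
            else:
                parts.append(tuple(sorted((a, d) for a, d, _ in rec["stays"])))
        elif "hospitals" in known:
            parts.append(tuple(sorted(h for _, _, h in rec["stays"])))
        sig = tuple(parts)
        sigs[pid] = sig
        keys[sig] = keys.get(sig, 0) + 1
    if not records:
        return float("nan")
    return float(np.mean([keys[sigs[pid]] == 1 for pid in records]))


def attack_success(
    scenario: str, cohort: Cohort, report: UniquenessReport
) -> float:
    """P(success) = P(access) x P(unique | cohort).

    ``random_target``: *report* must have been computed against the
    total dataset; ``target_in_cohort``: against the accessed cohort,
    and P(access) = 1.
    """
    if scenario not in ("random_target", "target_in_cohort"):
        raise ValueError(f"unknown scenario {scenario!r}")
    access = p_access(cohort, target_in_cohort=(scenario == "target_in_cohort"))
    report.scenario = scenario
    report.p_access_value = access
    return access * report.uniqueness


# -- k-suppression -------------------------------------------------------


def restrict(dataset: EHRDataset, patient_ids: set[str]) -> EHRDataset:
    """Sub-dataset containing only *patient_ids* (row order preserved)."""
    pat = dataset.patients[dataset.patients["patient_id"].isin(patient_ids)]
    stays = dataset.stays[dataset.stays["patient_id"].isin(patient_ids)]
    return EHRDataset(pat, stays, tuple(dataset.study_window), dataset.provenance)


def k_suppress(
    raw: EHRDataset,
    pseudo: EHRDataset,
    known: frozenset,
    params: SchemeParams,
    k_min: int,
    hospitals_as_set: bool = False,
) -> tuple[EHRDataset, float]:
    """Remove records until every survivor has k-anonymity >= k_min.

    k is recomputed on the surviving set after each pass, until a fixed
    point. Returns the surviving dataset and the fraction of patients
    removed. Pass ``pseudo = raw`` to suppress on unpseudonymised data
    (exact matching, amplitude 0).
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    true_records = patient_records(raw)
    all_records = patient_records(pseudo)
    surviving = set(all_records)
    n0 = len(surviving)
    while True:
        index = SearchIndex(
            {pid: all_records[pid] for pid in surviving}, known, params, hospitals_as_set
        )
        removed = {
            pid
            for pid in surviving
            if index.k_anonymity(AttackerKnowledge(known, true_records[pid])) < k_min
        }
        if not removed:
            break
        surviving -= removed
    fraction_removed = 1.0 - len(surviving) / n0 if n0 else 0.0
    return restrict(pseudo, surviving), fraction_removed


# -- ablation and stratification -----------------------------------------


def knowledge_ablation(
    raw: EHRDataset,
    pseudo: EHRDataset,
    params: SchemeParams,
    subsets: tuple[frozenset, ...] = NESTED_SUBSETS,
    target_ids: list[str] | None = None,
    sample_size: int | None = None,
    sample_seed: int = 0,
) -> pd.DataFrame:
    """Uniqueness per attacker-knowledge subset (same targets throughout)."""
    if not subsets:
        raise ValueError("subsets must be non-empty")
    rows = []
    for known in subsets:
        rep = uniqueness(
            raw, pseudo, known, params,
            target_ids=target_ids, sample_size=sample_size, sample_seed=sample_seed,
        )
        rows.append(
            {
                "knowledge": "+".join(sorted(known)),
                "n_attributes": len(known),
                "uniqueness": rep.uniqueness,
            }
        )
    return pd.DataFrame(rows)


def stratified_uniqueness(
    raw: EHRDataset,
    pseudo: EHRDataset,
    known: frozenset,
    params: SchemeParams,
    age_bands: list[tuple[float, float]],
    sample_size: int | None = None,
    sample_seed: int = 0,
) -> pd.DataFrame:
    """Uniqueness per band of age at first admission (true ages).

    Empty bands are reported with NaN uniqueness.
    """
    first = raw.first_admissions()
    report = uniqueness(
        raw, pseudo, known, params, sample_size=sample_size, sample_seed=sample_seed
    )
    ages = dict(zip(first["patient_id"], first["age_years"]))
    rows = []
    for lo, hi in age_bands:
        ks = [
            k
            for pid, k in report.per_record_k.items()
            if lo <= ages.get(pid, float("nan")) < hi
        ]
        rows.append(
            {
                "age_band": f"[{lo}, {hi})",
                "n_targets": len(ks),
                "uniqueness": float(np.mean([k == 1 for k in ks])) if ks else float("nan"),
            }
        )
    return pd.DataFrame(rows)
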