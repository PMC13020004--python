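"""Attack simulation: compatibility matching, k-anonymity, suppression."""

import itertools

import numpy as np
import pytest

from conftest import fuzz_pairs, make_dataset
from dateshift import (
    ATTRIBUTES,
    FULL_KNOWLEDGE,
    NESTED_SUBSETS,
    AttackerKnowledge,
    SchemeParams,
    SyntheticConfig,
    apply_scheme,
    compatible,
    compatible_bruteforce,
    exact_match_uniqueness,
    generate_population,
    k_anonymity,
    k_suppress,
    knowledge_ablation,
    patient_records,
    stratified_uniqueness,
    uniqueness,
)

BASE7 = SchemeParams("base", 7)


def _rec(sex="F", birth=0, death=None, stays=()):
    return {"sex": sex, "birth": birth, "death": death, "stays": sorted(stays)}


class TestCompatibility:
    def test_base_offset_within_range(self):
        know = AttackerKnowledge(FULL_KNOWLEDGE, _rec(stays=[(100, 103, 1)]))
        # delta = 5: every known date, including birth, shifts together
        assert compatible(know, _rec(birth=5, stays=[(105, 108, 1)]), BASE7)
        # same dates but an unshifted birth contradicts the shared offset
        assert not compatible(know, _rec(birth=0, stays=[(105, 108, 1)]), BASE7)

    def test_base_offset_out_of_range_or_wrong_los(self):
        know = AttackerKnowledge(
            frozenset({"sex", "stay_dates", "hospitals"}), _rec(stays=[(100, 103, 1)])
        )
        assert compatible(know, _rec(stays=[(105, 108, 1)]), BASE7)  # delta = 5
        assert not compatible(know, _rec(stays=[(108, 111, 1)]), BASE7)  # delta = 8
        assert not compatible(know, _rec(stays=[(105, 109, 1)]), BASE7)  # LOS 4 != 3

    def test_shared_offset_required_under_base_but_not_stay(self):
        target = _rec(stays=[(100, 103, 1), (200, 205, 1)])
        cand = _rec(stays=[(105, 108, 1), (206, 211, 1)])  # offsets 5 and 6
        know = AttackerKnowledge(frozenset({"sex", "stay_dates", "hospitals"}), target)
        assert not compatible(know, cand, BASE7)
        assert compatible(know, cand, SchemeParams("stay", 7))

    def test_sex_mismatch_fails(self):
        know = AttackerKnowledge(frozenset({"sex"}), _rec(sex="M"))
        assert not compatible(know, _rec(sex="F"), BASE7)
        assert compatible(know, _rec(sex="M"), BASE7)

    def test_death_presence_must_agree_when_known(self):
        know = AttackerKnowledge(frozenset({"sex", "death_date"}), _rec(death=300))
        assert not compatible(know, _rec(death=None), BASE7)
        assert compatible(know, _rec(death=305), BASE7)
        # death ignored entirely when unknown
        know2 = AttackerKnowledge(frozenset({"sex"}), _rec(death=300))
        assert compatible(know2, _rec(death=None), BASE7)

    def test_birth_scheme_relaxes_birth_only(self):
        params = SchemeParams("birth", 7, 100)
        target = _rec(birth=0, stays=[(100, 103, 1)])
        know = AttackerKnowledge(FULL_KNOWLEDGE, target)
        cand = _rec(birth=90, stays=[(105, 108, 1)])  # birth extra 85 <= 100
        assert compatible(know, cand, params)
        assert not compatible(know, cand, SchemeParams("base", 7))

    def test_tied_stays_with_hospitals_known(self):
        # two stays with identical dates but different hospitals
        target = _rec(stays=[(100, 103, 1), (100, 103, 2)])
        know = AttackerKnowledge(FULL_KNOWLEDGE, target)
        cand = _rec(birth=2, stays=[(102, 105, 2), (102, 105, 1)])
        assert compatible(know, cand, BASE7)
        assert compatible_bruteforce(know, cand, BASE7)
        swapped = _rec(birth=2, stays=[(102, 105, 3), (102, 105, 1)])
        assert not compatible(know, swapped, BASE7)

    def test_bruteforce_rejects_large_amplitudes(self):
        know = AttackerKnowledge(frozenset({"sex"}), _rec())
        with pytest.raises(ValueError, match="brute-force"):
            compatible_bruteforce(know, _rec(), SchemeParams("base", 1000))


def all_knowledge_subsets():
    return [
        frozenset(c)
        for n in range(1, len(ATTRIBUTES) + 1)
        for c in itertools.combinations(ATTRIBUTES, n)
    ]


@pytest.mark.parametrize("scheme", ["base", "birth", "stay"])
def test_matcher_equals_oracle_on_fuzzed_pairs(scheme):
    rng = np.random.default_rng(1234)
    subsets = all_knowledge_subsets()
    for dt in (0, 7, 30):
        params = SchemeParams(scheme, dt, dt if scheme == "birth" else 0)
        for target, cand in fuzz_pairs(rng, params, 60):
            for known in subsets:
                know = AttackerKnowledge(known, target)
                assert compatible(know, cand, params) == compatible_bruteforce(
                    know, cand, params
                ), (scheme, dt, sorted(known), target, cand)


@pytest.mark.parametrize("scheme", ["base", "birth", "stay"])
def test_compatibility_monotone_in_evaluated_amplitude(scheme):
    rng = np.random.default_rng(77)
    small = SchemeParams(scheme, 7, 7 if scheme == "birth" else 0)
    large = SchemeParams(scheme, 30, 30 if scheme == "birth" else 0)
    hits = 0
    for target, cand in fuzz_pairs(rng, small, 150):
        know = AttackerKnowledge(FULL_KNOWLEDGE, target)
        if compatible(know, cand, small):
            hits += 1
            assert compatible(know, cand, large)
    assert hits > 10  # the sweep actually exercised compatible pairs


class TestKAnonymity:
    def test_exact_copies_counted(self):
        rec = _rec(stays=[(100, 103, 1)])
        search = {f"p{i}": rec for i in range(5)}
        know = AttackerKnowledge(FULL_KNOWLEDGE, rec)
        assert k_anonymity(know, search, SchemeParams("base", 0)) == 5

    def test_sex_isolates_single_record(self):
        target = _rec(sex="M", stays=[(100, 103, 1)])
        search = {"t": target, **{f"p{i}": _rec(sex="F", stays=[(100, 103, 1)]) for i in range(4)}}
        know = AttackerKnowledge(frozenset({"sex"}), target)
        assert k_anonymity(know, search, BASE7) == 1

    def test_blocked_search_equals_bruteforce_count(self):
        ds = generate_population(SyntheticConfig(n_patients=200, seed=6))
        params = SchemeParams("base", 30)
        pseudo = apply_scheme(ds, params, seed=8)
        true_recs = patient_records(ds)
        search = patient_records(pseudo)
        rng = np.random.default_rng(0)
        for pid in rng.choice(sorted(true_recs), 30, replace=False):
            know = AttackerKnowledge(FULL_KNOWLEDGE, true_recs[pid])
            fast = k_anonymity(know, search, params)
            slow = sum(
                compatible_bruteforce(know, rec, params) for rec in search.values()
            )
            assert fast == slow


class TestUniqueness:
    def test_duplicated_records_are_never_unique(self):
        ds = make_dataset(
            [("p1", "F", 0, np.nan), ("p2", "F", 0, np.nan)],
            [("s1", "p1", 100, 103, 1, ""), ("s2", "p2", 100, 103, 1, "")],
        )
        report = uniqueness(ds, ds, FULL_KNOWLEDGE, SchemeParams("base", 0))
        assert report.uniqueness == 0.0
        assert report.k_histogram == {2: 2}

    def test_far_apart_patients_all_unique(self):
        ds = make_dataset(
            [(f"p{i}", "F", 0, np.nan) for i in range(3)],
            [(f"s{i}", f"p{i}", d, d + 2, 1, "") for i, d in enumerate((0, 1000, 2000))],
        )
        pseudo = apply_scheme(ds, BASE7, seed=3)
        report = uniqueness(ds, pseudo, FULL_KNOWLEDGE, BASE7)
        assert report.uniqueness == 1.0

    def test_empty_target_set_rejected(self, pop_small):
        with pytest.raises(ValueError, match="empty target set"):
            uniqueness(pop_small, pop_small, FULL_KNOWLEDGE, BASE7, target_ids=[])

    def test_zero_amplitude_equals_exact_matching(self, pop_small):
        params = SchemeParams("base", 0)
        pseudo = apply_scheme(pop_small, params, seed=1)
        for known in (FULL_KNOWLEDGE, frozenset({"sex", "birth_date"})):
            report = uniqueness(pop_small, pseudo, known, params)
            assert report.uniqueness == exact_match_uniqueness(pop_small, known)


def test_success_probability_arithmetic():
    from dateshift import attack_success
    from dateshift.cohorts import Cohort, CohortCriteria
    from dateshift.attacks import UniquenessReport

    cohort = Cohort(CohortCriteria(), frozenset(f"p{i}" for i in range(500)), n_total=2000)
    report = UniquenessReport({f"p{i}": (1 if i < 50 else 2) for i in range(100)})
    assert report.uniqueness == 0.5
    assert attack_success("random_target", cohort, report) == 0.25 * 0.5
    assert attack_success("target_in_cohort", cohort, report) == 0.5
    assert report.p_success == report.p_access_value * report.uniqueness
    zero = UniquenessReport({"a": 2, "b": 3})
    assert attack_success("random_target", cohort, zero) == 0.0
    with pytest.raises(ValueError):
        attack_success("nonsense", cohort, report)


class TestKSuppression:
    def test_identical_records_survive(self):
        ds = make_dataset(
            [(f"p{i}", "F", 0, np.nan) for i in range(10)],
            [(f"s{i}", f"p{i}", 100, 103, 1, "") for i in range(10)],
        )
        surviving, frac = k_suppress(ds, ds, FULL_KNOWLEDGE, SchemeParams("base", 0), 5)
        assert frac == 0.0 and surviving.n_patients == 10

    def test_all_distinct_records_removed(self):
        ds = make_dataset(
            [(f"p{i}", "F", 0, np.nan) for i in range(6)],
            [(f"s{i}", f"p{i}", 100 * i, 100 * i + 2, 1, "") for i in range(6)],
        )
        surviving, frac = k_suppress(ds, ds, FULL_KNOWLEDGE, SchemeParams("base", 0), 5)
        assert frac == 1.0 and surviving.n_patients == 0

    def test_fixed_point_matches_bruteforce_recomputation(self):
        ds = generate_population(SyntheticConfig(n_patients=250, seed=9))
        params = SchemeParams("base", 0)
        known = frozenset({"sex", "hospitals"})
        surviving, frac = k_suppress(ds, ds, known, params, 5)
        # independent fixed-point recomputation with the brute-force matcher
        records = patient_records(ds)
        alive = set(records)
        while True:
            removed = set()
            for pid in alive:
                know = AttackerKnowledge(known, records[pid])
                k = sum(
                    compatible_bruteforce(know, records[q], params) for q in alive
                )
                if k < 5:
                    removed.add(pid)
            if not removed:
                break
            alive -= removed
        assert set(surviving.patients["patient_id"]) == alive
        assert frac == 1.0 - len(alive) / len(records)

    def test_k_min_validated(self, pop_small):
        with pytest.raises(ValueError):
            k_suppress(pop_small, pop_small, FULL_KNOWLEDGE, BASE7, 1)


def test_knowledge_ablation_monotone_on_fixed_data(pop_small):
    params = SchemeParams("birth", 30, 30)
    pseudo = apply_scheme(pop_small, params, seed=4)
    table = knowledge_ablation(pop_small, pseudo, params, NESTED_SUBSETS)
    assert table["uniqueness"].is_monotonic_increasing


def test_stratified_uniqueness_bands(pop_small):
    params = SchemeParams("base", 7)
    pseudo = apply_scheme(pop_small, params, seed=4)
    whole = stratified_uniqueness(
        pop_small, pseudo, FULL_KNOWLEDGE, params, [(0.0, float("inf"))]
    )
    overall = uniqueness(pop_small, pseudo, FULL_KNOWLEDGE, params).uniqueness
    assert whole.loc[0, "uniqueness"] == overall
    with_empty = stratified_uniqueness(
        pop_small, pseudo, FULL_KNOWLEDGE, params, [(0.0, 200.0), (200.0, 300.0)]
    )
    assert np.isnan(with_empty.loc[1, "uniqueness"])
    assert with_empty.loc[0, "uniqueness"] == overall


def test_base_self_compatibility_invariant_to_redrawn_seeds(pop_small):
    # the attacker exploits only the offset range, never the realised draw:
    # a target matches its own record under every seed
    params = SchemeParams("base", 30)
    true_recs = patient_records(pop_small)
    for seed in (1, 2, 3):
        pseudo_recs = patient_records(apply_scheme(pop_small, params, seed=seed))
        for pid in list(true_recs)[:50]:
            know = AttackerKnowledge(FULL_KNOWLEDGE, true_recs[pid])
            assert compatible(know, pseudo_recs[pid], params)
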