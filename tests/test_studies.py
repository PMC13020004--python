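"""Study statistics, KM/Cox correctness, KL divergence, pathway clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset
from dateshift import (
    SchemeParams,
    apply_scheme,
    kl_divergence,
    study_bariatric,
    study_care_pathways,
    study_epidemic,
    study_hosp_characterisation,
    study_survival,
    unreliability,
)


class TestCharacterisation:
    def test_rehospitalisation_is_per_discharge(self):
        ds = make_dataset(
            [("p1", "F", 0, np.nan)],
            [("s1", "p1", 95, 100, 1, ""), ("s2", "p1", 150, 152, 1, "")],
        )
        stats = study_hosp_characterisation(ds).statistics
        # first discharge followed within 90 days, last discharge is not
        assert stats["rehosp_3m_rate"] == 0.5

    def test_constant_age_has_zero_sd(self):
        days_40y = int(round(40 * 365.25))
        ds = make_dataset(
            [(f"p{i}", "F", 0, np.nan) for i in range(3)],
            [(f"s{i}", f"p{i}", days_40y, days_40y + 1, 1, "") for i in range(3)],
        )
        stats = study_hosp_characterisation(ds).statistics
        assert stats["mean_age_first_admission"] == pytest.approx(40.0, abs=0.01)
        assert stats["sd_age_first_admission"] == 0.0

    def test_empty_dataset_rejected(self):
        ds = make_dataset([("p1", "F", 0, np.nan)], [])
        with pytest.raises(ValueError):
            study_hosp_characterisation(ds)


class TestEpidemicSeries:
    def test_single_week_spike(self):
        ds = make_dataset(
            [(f"p{i}", "F", 0, np.nan) for i in range(4)],
            [(f"s{i}", f"p{i}", 70 + i, 71 + i, 1, "J21.0") for i in range(4)],
            window=(0, 140),
        )
        series = study_epidemic(ds, "J21").series
        assert series[10] == 4 and series.sum() == 4

    def test_seven_day_shift_translates_by_one_bin(self):
        stays = [(f"s{i}", f"p{i}", 70 + 7 * i, 71 + 7 * i, 1, "J21.0") for i in range(5)]
        pats = [(f"p{i}", "F", 0, np.nan) for i in range(5)]
        ds = make_dataset(pats, stays, window=(0, 140))
        shifted = make_dataset(
            pats,
            [(s, p, a + 7, d + 7, h, c) for s, p, a, d, h, c in stays],
            window=(0, 140),
        )
        a = study_epidemic(ds, "J21").series
        b = study_epidemic(shifted, "J21").series
        assert (np.roll(a, 1) == b).all()


class TestKLDivergence:
    def test_identical_series_zero(self):
        s = np.array([3, 1, 4, 1, 5])
        assert kl_divergence(s, s) == 0.0

    def test_closed_form_value(self):
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75], epsilon=0.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.1438, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.integers(0, 50), min_size=3, max_size=12),
        q=st.lists(st.integers(0, 50), min_size=3, max_size=12),
    )
    def test_non_negative_on_fuzzed_series(self, p, q):
        n = min(len(p), len(q))
        assert kl_divergence(p[:n], q[:n]) >= 0.0


class TestBariatric:
    def test_thirty_day_boundary_closed(self):
        for delay, counted in ((30, 1.0), (31, 0.0)):
            ds = make_dataset(
                [("p1", "F", 0, np.nan)],
                [
                    ("s1", "p1", 100, 105, 1, "K95.0"),
                    ("s2", "p1", 105 + delay, 106 + delay, 1, ""),
                ],
            )
            assert study_bariatric(ds).statistics["readmit_30d_rate"] == counted

    def test_no_index_stays_rejected(self):
        ds = make_dataset([("p1", "F", 0, np.nan)], [("s1", "p1", 1, 2, 1, "")])
        with pytest.raises(ValueError):
            study_bariatric(ds)


def _survival_fixture():
    # 4 diagnoses at day 0; deaths at 10, 20, 30; one censored (alive, last
    # contact day 40)
    pats = [
        ("p1", "F", -30000, 10.0),
        ("p2", "M", -30000, 20.0),
        ("p3", "F", -30000, 30.0),
        ("p4", "M", -30000, np.nan),
    ]
    stays = [
        ("s1", "p1", 0, 2, 1, "C25.0;TRT_BSC"),
        ("s2", "p2", 0, 2, 1, "C25.0;TRT_BSC"),
        ("s3", "p3", 0, 2, 1, "C25.0;TRT_BSC"),
        ("s4", "p4", 0, 2, 1, "C25.0;TRT_BSC"),
        ("s5", "p4", 38, 40, 1, ""),
    ]
    return make_dataset(pats, stays, window=(0, 100))


class TestSurvival:
    def test_product_limit_hand_computation(self):
        result = study_survival(_survival_fixture(), window_filter=False)
        curve = result.curve.set_index("time")["survival"]
        assert curve.loc[10.0] == pytest.approx(0.75)
        assert curve.loc[20.0] == pytest.approx(0.50)
        assert curve.loc[30.0] == pytest.approx(0.25)

    def test_all_censored_curve_stays_at_one(self):
        ds = make_dataset(
            [(f"p{i}", "F", -30000, np.nan) for i in range(4)],
            [(f"s{i}", f"p{i}", 0, 2, 1, "C25.0;TRT_BSC") for i in range(4)],
            window=(0, 100),
        )
        result = study_survival(ds, window_filter=False)
        assert result.statistics["n_events"] == 0
        assert (result.curve["survival"] == 1.0).all()

    def test_empty_cohort_rejected(self):
        ds = make_dataset([("p1", "F", 0, np.nan)], [("s1", "p1", 1, 2, 1, "")])
        with pytest.raises(ValueError):
            study_survival(ds)


class TestCarePathways:
    @staticmethod
    def _two_archetypes(n_per=40):
        # archetype A: frequent short stays at hospital 1;
        # archetype B: rare long stays at hospital 2
        pats, stays, sid = [], [], 0
        for i in range(n_per):
            pid = f"a{i}"
            pats.append((pid, "F", -20000 - 10 * i, np.nan))
            for j in range(6):
                stays.append((f"s{sid}", pid, 100 + 60 * j + i, 101 + 60 * j + i, 1, "C25.0"))
                sid += 1
        for i in range(n_per):
            pid = f"b{i}"
            pats.append((pid, "M", -25000 - 10 * i, np.nan))
            for j in range(2):
                stays.append(
                    (f"s{sid}", pid, 100 + 300 * j + i, 115 + 300 * j + i, 2, "C25.0")
                )
                sid += 1
        return make_dataset(pats, stays)

    def test_planted_archetypes_recovered(self):
        ds = self._two_archetypes()
        result = study_care_pathways(ds, k_clusters=2)
        members = result.memberships.set_index("patient_id")["cluster"]
        label_a = members.loc[[f"a{i}" for i in range(40)]]
        label_b = members.loc[[f"b{i}" for i in range(40)]]
        majority_a = label_a.mode()[0]
        majority_b = label_b.mode()[0]
        assert majority_a != majority_b
        recovery = ((label_a == majority_a).mean() + (label_b == majority_b).mean()) / 2
        assert recovery >= 0.95

    def test_single_cluster_contains_everyone(self):
        ds = self._two_archetypes(10)
        result = study_care_pathways(ds, k_clusters=1)
        assert (result.memberships["cluster"] == 0).all()
        assert result.descriptors.loc[0, "n_patients"] == 20

    def test_membership_invariant_to_patient_order(self):
        ds = self._two_archetypes(15)
        shuffled = make_dataset(
            list(ds.patients.sample(frac=1, random_state=3).itertuples(index=False)),
            list(ds.stays.sample(frac=1, random_state=4).itertuples(index=False)),
        )
        a = study_care_pathways(ds, k_clusters=2).memberships.set_index("patient_id")
        b = study_care_pathways(shuffled, k_clusters=2).memberships.set_index("patient_id")
        joined = a.join(b, lsuffix="_a", rsuffix="_b")
        # identical partition up to label permutation
        mapping = joined.groupby("cluster_a")["cluster_b"].nunique()
        assert (mapping == 1).all()

    def test_fewer_patients_than_clusters_rejected(self):
        ds = self._two_archetypes(1)
        with pytest.raises(ValueError):
            study_care_pathways(ds, k_clusters=5)


class TestUnreliability:
    def test_identical_results_score_zero(self):
        r = study_hosp_characterisation(
            make_dataset([("p1", "F", 0, np.nan)], [("s1", "p1", 100, 103, 1, "")])
        )
        assert unreliability(r, r).value == 0.0

    def test_mean_relative_deviation_formula(self):
        from dateshift.studies import StudyResult

        a = StudyResult("x", {"mean_age": 50.0, "rate": 0.10})
        b = StudyResult("x", {"mean_age": 55.0, "rate": 0.10})
        score = unreliability(a, b)
        assert score.value == pytest.approx(0.05)
        assert score.components == {"mean_age": 0.1, "rate": 0.0}

    def test_zero_original_with_nonzero_pseudo_flagged(self):
        from dateshift.studies import StudyResult

        a = StudyResult("x", {"rate": 0.0})
        b = StudyResult("x", {"rate": 0.2})
        score = unreliability(a, b)
        assert np.isinf(score.components["rate"]) and score.flags

    def test_study_type_mismatch_rejected(self):
        from dateshift.studies import StudyResult

        with pytest.raises(ValueError):
            unreliability(StudyResult("x", {"a": 1}), StudyResult("y", {"a": 1}))

    def test_base_scheme_invariance_for_scalar_studies(self, full_small):
        pseudo = apply_scheme(full_small, SchemeParams("base", 250), seed=5)
        for fn in (study_hosp_characterisation, study_bariatric):
            assert unreliability(fn(full_small), fn(pseudo)).value == 0.0
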