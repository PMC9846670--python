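"""First-event cohort construction and cohort comparison statistics."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenokit import (
    Cohort,
    PhenokitError,
    StudyConfig,
    build_cohort,
    build_graph,
    build_primary,
    cohort_metrics,
    compare_cohorts,
    compare_demographics,
    generate_patients,
    generate_random_ontology,
)
from phenokit.cohort import age_at_midpoint, eligible_patients
from phenokit.fixtures import FixtureSpec, RANDOM_ID_BASE

CONFIG = StudyConfig(study_start=date(2013, 1, 1), study_end=date(2018, 12, 31))


def make_cohort(name, patient_ids, dates=None):
    dates = dates or ["2015-01-01"] * len(patient_ids)
    return Cohort(
        name,
        pd.DataFrame(
            {"patient_id": list(patient_ids), "first_event_date": pd.to_datetime(dates)}
        ),
    )


def demo_row(pid, sex="female", birth_year=1960,
             reg_start="2010-01-01", reg_end="2018-12-31"):
    return {
        "patient_id": pid, "sex": sex, "birth_year": birth_year,
        "reg_start": reg_start, "reg_end": reg_end,
    }


class TestBuildCohort:
    def _codelist(self, table1):
        from phenokit.fixtures import BRONCHIECTASIS
        return build_primary(table1.graph, {BRONCHIECTASIS})

    def test_earliest_event_date_kept(self, table1):
        events = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "code": ["12295008", "23022004"],
                "event_date": ["2014-05-01", "2013-02-01"],
            }
        )
        demographics = pd.DataFrame([demo_row(1)])
        cohort = build_cohort(
            events, demographics, self._codelist(table1), config=CONFIG
        )
        assert len(cohort) == 1
        assert cohort.members.loc[0, "first_event_date"] == pd.Timestamp("2013-02-01")

    def test_minor_excluded_by_age_rule(self, table1):
        events = pd.DataFrame(
            {"patient_id": [1], "code": ["12295008"], "event_date": ["2014-05-01"]}
        )
        demographics = pd.DataFrame([demo_row(1, birth_year=1997)])
        # age at the 2014-mid registration midpoint is ~17
        cohort = build_cohort(
            events, demographics, self._codelist(table1), config=CONFIG
        )
        assert len(cohort) == 0

    def test_insufficient_followup_excluded(self, table1):
        events = pd.DataFrame(
            {"patient_id": [1], "code": ["12295008"], "event_date": ["2018-10-01"]}
        )
        demographics = pd.DataFrame(
            [demo_row(1, reg_start="2018-06-01", reg_end="2018-12-31")]
        )
        cohort = build_cohort(
            events, demographics, self._codelist(table1), config=CONFIG
        )
        assert len(cohort) == 0

    def test_event_outside_codelist_ignored(self, table1):
        events = pd.DataFrame(
            {"patient_id": [1], "code": ["187251001"], "event_date": ["2014-05-01"]}
        )
        demographics = pd.DataFrame([demo_row(1)])
        cohort = build_cohort(
            events, demographics, self._codelist(table1), config=CONFIG
        )
        assert len(cohort) == 0

    def test_local_code_dictionary_resolution(self, table1):
        events = pd.DataFrame(
            {"patient_id": [1, 2], "code": ["m100001", "zzz"],
             "event_date": ["2014-05-01", "2014-05-01"]}
        )
        demographics = pd.DataFrame([demo_row(1), demo_row(2)])
        cohort = build_cohort(
            events, demographics, self._codelist(table1),
            dictionary=table1.mappings, config=CONFIG,
        )
        assert cohort.patient_ids == {1}  # unmapped code logged, not fatal

    def test_matches_per_patient_loop_oracle(self):
        spec = FixtureSpec(
            n_concepts=20, seed=11, n_patients=400,
            prevalence_by_concept={RANDOM_ID_BASE: 0.3},
        )
        release = generate_random_ontology(spec)
        graph = build_graph(release)
        events, demographics = generate_patients(release, spec)
        codelist = build_primary(graph, {RANDOM_ID_BASE})
        cohort = build_cohort(events, demographics, codelist, config=CONFIG)

        # straightforward per-patient reimplementation
        inclusion = codelist.inclusion_ids
        expected = {}
        demo_by_id = {r["patient_id"]: r for _, r in demographics.iterrows()}
        for _, ev in events.iterrows():
            d = demo_by_id[ev["patient_id"]]
            mid = (
                pd.Timestamp(d["reg_start"])
                + (pd.Timestamp(d["reg_end"]) - pd.Timestamp(d["reg_start"])) / 2
            )
            age = (mid - pd.Timestamp(int(d["birth_year"]), 7, 2)).days / 365.25
            start = max(pd.Timestamp(d["reg_start"]), pd.Timestamp("2013-01-01"))
            end = min(pd.Timestamp(d["reg_end"]), pd.Timestamp("2018-12-31"))
            followup = (end - start).days / 365.25
            if age <= 18 or followup < 1:
                continue
            if int(ev["code"]) not in inclusion:
                continue
            when = pd.Timestamp(ev["event_date"])
            pid = ev["patient_id"]
            expected[pid] = min(expected.get(pid, when), when)
        assert cohort.patient_ids == set(expected)
        got = dict(
            zip(cohort.members["patient_id"], cohort.members["first_event_date"])
        )
        assert got == expected


class TestCohortMetrics:
    def test_identical_cohorts_are_perfect(self):
        a = make_cohort("a", [1, 2, 3])
        m = cohort_metrics(a, a)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
        assert m.tp + m.fp == m.n_test
        assert m.tp + m.fn == m.n_gold

    def test_hand_computed_overlap(self):
        gold = make_cohort("gold", [1, 2, 3, 4])
        test = make_cohort("test", [1, 2, 3, 5, 6])
        m = cohort_metrics(test, gold)
        assert m.precision == pytest.approx(0.6)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_disjoint_cohorts_score_zero(self):
        m = cohort_metrics(make_cohort("t", [1, 2]), make_cohort("g", [3, 4]))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_empty_cohort_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            m = cohort_metrics(make_cohort("t", []), make_cohort("g", [1]))
        assert m.precision == 0.0
        assert "empty cohort" in caplog.text

    def test_wilson_interval_brackets_estimate(self):
        gold = make_cohort("gold", range(100))
        test = make_cohort("test", range(80))  # tp=80, fn=20
        m = cohort_metrics(test, gold)
        lo, hi = m.recall_ci
        assert lo < m.recall < hi
        # Wilson interval for 80/100 (hand-checked against the closed form)
        z = stats.norm.ppf(0.975)
        centre = (0.8 + z**2 / 200) / (1 + z**2 / 100)
        half = (
            z * np.sqrt(0.8 * 0.2 / 100 + z**2 / (4 * 100**2)) / (1 + z**2 / 100)
        )
        assert lo == pytest.approx(centre - half)
        assert hi == pytest.approx(centre + half)

    def test_f1_symmetric_and_pr_swap(self):
        gold = make_cohort("gold", [1, 2, 3, 4])
        test = make_cohort("test", [3, 4, 5])
        ab = cohort_metrics(test, gold)
        ba = cohort_metrics(gold, test)
        assert ab.f1 == pytest.approx(ba.f1)
        assert ab.precision == pytest.approx(ba.recall)
        assert ab.recall == pytest.approx(ba.precision)

    def test_adding_gold_member_never_decreases_recall(self):
        gold = make_cohort("gold", [1, 2, 3, 4])
        test = make_cohort("test", [1, 5])
        grown = make_cohort("test", [1, 2, 5])
        assert cohort_metrics(grown, gold).recall >= cohort_metrics(test, gold).recall

    def test_adding_non_gold_member_never_increases_precision(self):
        gold = make_cohort("gold", [1, 2, 3, 4])
        test = make_cohort("test", [1, 2])
        grown = make_cohort("test", [1, 2, 99])
        assert (
            cohort_metrics(grown, gold).precision
            <= cohort_metrics(test, gold).precision
        )


class TestCompareDemographics:
    def test_identical_cohorts_have_zero_differences(self):
        demographics = pd.DataFrame(
            [demo_row(1, "female", 1950), demo_row(2, "male", 1940)]
        )
        c = make_cohort("c", [1, 2])
        d = compare_demographics(c, c, demographics)
        assert d.sex_proportion_diff == 0.0
        assert d.mean_age_diff == 0.0
        assert d.sex_p == 1.0

    def test_welch_interval_matches_hand_formula(self):
        demographics = pd.DataFrame(
            [
                demo_row(1, "female", 1950), demo_row(2, "female", 1940),
                demo_row(3, "female", 1960), demo_row(4, "female", 1950),
            ]
        )
        gold = make_cohort("gold", [1, 2])
        test = make_cohort("test", [3, 4])
        d = compare_demographics(test, gold, demographics)

        ages = age_at_midpoint(demographics).to_numpy()
        g, t = ages[:2], ages[2:]
        diff = g.mean() - t.mean()
        v_g, v_t = g.var(ddof=1), t.var(ddof=1)
        se = np.sqrt(v_g / 2 + v_t / 2)
        df = (v_g / 2 + v_t / 2) ** 2 / (
            (v_g / 2) ** 2 / 1 + (v_t / 2) ** 2 / 1
        )
        margin = stats.t.ppf(0.975, df) * se
        assert d.mean_age_diff == pytest.approx(diff)
        assert d.mean_age_diff == pytest.approx(10.0, abs=0.05)
        assert d.age_diff_ci == (
            pytest.approx(diff - margin), pytest.approx(diff + margin)
        )

    def test_balanced_proportions_give_symmetric_interval(self):
        rows = [
            demo_row(i, "female" if i % 2 else "male", 1950) for i in range(200)
        ]
        demographics = pd.DataFrame(rows)
        gold = make_cohort("gold", range(0, 100))
        test = make_cohort("test", range(100, 200))
        d = compare_demographics(test, gold, demographics)
        assert d.sex_proportion_diff == 0.0
        lo, hi = d.sex_diff_ci
        assert lo == pytest.approx(-hi)

    def test_missing_demographics_row_names_patient(self):
        demographics = pd.DataFrame([demo_row(1)])
        with pytest.raises(PhenokitError, match="patient 2"):
            compare_demographics(
                make_cohort("t", [1, 2]), make_cohort("g", [1]), demographics
            )

    def test_difference_oriented_gold_minus_test(self):
        demographics = pd.DataFrame(
            [demo_row(1, "female"), demo_row(2, "male"),
             demo_row(3, "male"), demo_row(4, "male")]
        )
        gold = make_cohort("gold", [1, 2])  # 50% female
        test = make_cohort("test", [3, 4])  # 0% female
        d = compare_demographics(test, gold, demographics)
        assert d.sex_proportion_diff == pytest.approx(0.5)

    def test_wald_interval_coverage_is_nominal(self):
        # 1000 two-proportion simulations; the 95% Wald interval should
        # cover the true difference about 95% of the time
        rng = np.random.default_rng(2024)
        p_gold, p_test, n = 0.55, 0.45, 200
        true_diff = p_gold - p_test
        z = stats.norm.ppf(0.975)
        covered = 0
        for _ in range(1000):
            x_g = rng.binomial(n, p_gold)
            x_t = rng.binomial(n, p_test)
            pg, pt = x_g / n, x_t / n
            se = np.sqrt(pg * (1 - pg) / n + pt * (1 - pt) / n)
            lo, hi = (pg - pt) - z * se, (pg - pt) + z * se
            covered += lo <= true_diff <= hi
        assert 930 <= covered <= 970

        # spot-check one replicate against compare_demographics
        rows = [demo_row(i, "female" if i < 110 else "male") for i in range(200)]
        rows += [demo_row(200 + i, "female" if i < 90 else "male") for i in range(200)]
        demographics = pd.DataFrame(rows)
        d = compare_demographics(
            make_cohort("t", range(200, 400)),
            make_cohort("g", range(200)),
            demographics,
        )
        pg, pt = 110 / 200, 90 / 200
        se = np.sqrt(pg * (1 - pg) / 200 + pt * (1 - pt) / 200)
        assert d.sex_proportion_diff == pytest.approx(0.1)
        assert d.sex_diff_ci == (
            pytest.approx(0.1 - z * se), pytest.approx(0.1 + z * se)
        )


class TestCompareCohorts:
    def test_combines_metrics_and_demographics(self):
        demographics = pd.DataFrame(
            [demo_row(i, "female" if i % 2 else "male", 1940 + i) for i in range(1, 7)]
        )
        gold = make_cohort("gold", [1, 2, 3, 4])
        test = make_cohort("test", [1, 2, 3, 5, 6])
        out = compare_cohorts(test, gold, demographics)
        assert out.precision == pytest.approx(0.6)
        assert out.mean_age_diff is not None
        assert out.metadata["ci_method"] == "wilson"
        assert out.metadata["age_ci_method"] == "welch"
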