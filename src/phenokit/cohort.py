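"""First-event cohorts and cohort-against-cohort evaluation.

A phenotype codelist is applied to a patient event table to form a
*first-event cohort*: every eligible patient with at least one coded
event whose concept falls in the codelist's inclusion set, carrying the
earliest such event date. Eligibility mimics primary-care research
database practice: adult at the midpoint of the registration interval,
registration overlapping the study window with a minimum of follow-up.

Two cohorts over the same population are compared by patient-level
precision, recall and F1 (membership by patient id, one cohort acting as
gold standard) with Wilson 95% intervals, and by demographics: the
difference in the proportion of female patients (Wald interval, two-sided
z test) and the difference in mean age at the registration midpoint
(Welch interval and t test). Differences are oriented gold minus test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .codelist import Codelist
from .errors import PhenokitError
from .rf2 import MappingRow

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StudyConfig:
    """Eligibility rules for cohort construction.

    min_age_years is a strict lower bound ("aged over 18") on age at the
    registration-interval midpoint; min_followup_years is required between
    max(reg_start, study_start) and min(reg_end, study_end).
    """

    study_start: date
    study_end: date
    min_age_years: float = 18.0
    min_followup_years: float = 1.0

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")


@dataclass
class Cohort:
    """Patients selected by a codelist, with first qualifying event dates."""

    name: str
    members: pd.DataFrame  # columns: patient_id, first_event_date

    @property
    def patient_ids(self) -> set:
        return set(self.members["patient_id"])

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CohortComparison:
    """Patient-level agreement and demographic comparison of two cohorts.

    Fields are filled by :func:`cohort_metrics` (counts, precision/recall/
    F1) and :func:`compare_demographics` (sex and age differences); a field
    a given function does not compute stays None. The paper-style report
    gives intervals for precision and recall but F1 only as a point
    estimate. ``metadata`` records the interval/test methods used.
    """

    n_gold: Optional[int] = None
    n_test: Optional[int] = None
    tp: Optional[int] = None
    fp: Optional[int] = None
    fn: Optional[int] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    precision_ci: Optional[tuple[float, float]] = None
    recall_ci: Optional[tuple[float, float]] = None
    f1_ci: Optional[tuple[float, float]] = None
    sex_proportion_diff: Optional[float] = None
    sex_diff_ci: Optional[tuple[float, float]] = None
    sex_p: Optional[float] = None
    mean_age_diff: Optional[float] = None
    age_diff_ci: Optional[tuple[float, float]] = None
    age_p: Optional[float] = None
    metadata: dict = field(default_factory=dict)


def _as_concept_map(
    dictionary: Optional[Iterable[MappingRow]],
) -> Optional[Mapping[str, int]]:
    if dictionary is None:
        return None
    if isinstance(dictionary, Mapping):
        return dictionary
    out: dict[str, int] = {}
    for m in dictionary:
        if m.local_code is not None:
            out[str(m.local_code)] = m.concept_id
    return out


def registration_midpoint(reg_start: pd.Series, reg_end: pd.Series) -> pd.Series:
    return reg_start + (reg_end - reg_start) / 2


def age_at_midpoint(demographics: pd.DataFrame) -> pd.Series:
    """Age in years at the registration-interval midpoint.

    Birth dates are known only to the year (privacy-preserving), so age is
    measured from the birth-year midpoint (July 2) in units of 365.25 days.
    """
    mid = registration_midpoint(
        pd.to_datetime(demographics["reg_start"]),
        pd.to_datetime(demographics["reg_end"]),
    )
    birth_mid = pd.to_datetime(
        {
            "year": demographics["birth_year"].astype(int),
            "month": 7,
            "day": 2,
        }
    )
    return (mid - birth_mid).dt.days / DAYS_PER_YEAR


def eligible_patients(
    demographics: pd.DataFrame, config: StudyConfig
) -> pd.Series:
    """Patient ids meeting the age and follow-up eligibility rules."""
    demo = demographics.copy()
    reg_start = pd.to_datetime(demo["reg_start"])
    reg_end = pd.to_datetime(demo["reg_end"])
    if (reg_start > reg_end).any():
        bad = demo.loc[reg_start > reg_end, "patient_id"].iloc[0]
        raise PhenokitError(f"patient {bad}: reg_start after reg_end")
    age = age_at_midpoint(demo)
    start = reg_start.clip(lower=pd.Timestamp(config.study_start))
    end = reg_end.clip(upper=pd.Timestamp(config.study_end))
    followup_years = (end - start).dt.days / DAYS_PER_YEAR
    ok = (age > config.min_age_years) & (
        followup_years >= config.min_followup_years
    )
    return demo.loc[ok, "patient_id"]


def build_cohort(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    codelist: Codelist,
    dictionary: Optional[Union[Iterable[MappingRow], Mapping[str, int]]] = None,
    config: Optional[StudyConfig] = None,
    name: Optional[str] = None,
) -> Cohort:
    """Select the first-event cohort of a codelist.

    ``events`` has columns patient_id, code, event_date. Codes are
    resolved to concept ids through ``dictionary`` (a local-code mapping)
    when given, otherwise interpreted as concept ids directly; events with
    unresolvable codes are counted and logged, not fatal. The earliest
    matching event per eligible patient is kept regardless of its date
    (prevalent/historic phenotyping).
    """
    ev = events.copy()
    concept_map = _as_concept_map(dictionary)
    if concept_map is not None:
        resolved = ev["code"].astype(str).map(concept_map)
        n_unmapped = int(resolved.isna().sum())
        if n_unmapped:
            logger.warning(
                "%d event row(s) had codes absent from the dictionary", n_unmapped
            )
        ev = ev[resolved.notna()].copy()
        ev["concept_id"] = resolved[resolved.notna()].astype("int64")
    else:
        ev["concept_id"] = pd.to_numeric(ev["code"], errors="coerce")
        n_unmapped = int(ev["concept_id"].isna().sum())
        if n_unmapped:
            logger.warning("%d event row(s) had non-numeric codes", n_unmapped)
        ev = ev[ev["concept_id"].notna()].copy()
        ev["concept_id"] = ev["concept_id"].astype("int64")

    inclusion = codelist.inclusion_ids
    ev = ev[ev["concept_id"].isin(inclusion)]
    if config is not None:
        eligible = set(eligible_patients(demographics, config))
        ev = ev[ev["patient_id"].isin(eligible)]
    ev = ev.assign(event_date=pd.to_datetime(ev["event_date"]))
    firsts = (
        ev.groupby("patient_id", as_index=False)["event_date"]
        .min()
        .rename(columns={"event_date": "first_event_date"})
        .sort_values("patient_id", ignore_index=True)
    )
    return Cohort(name=name or codelist.name, members=firsts)


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def cohort_metrics(test: Cohort, gold: Cohort) -> CohortComparison:
    """Patient-level precision/recall/F1 of a test cohort against a gold
    cohort (membership by patient id), with Wilson 95% intervals.

    Empty cohorts yield zero metrics with degenerate intervals and a
    warning rather than an error.
    """
    t, g = test.patient_ids, gold.patient_ids
    tp = len(t & g)
    n_test, n_gold = len(t), len(g)
    if n_test == 0 or n_gold == 0:
        logger.warning(
            "empty cohort in comparison (test n=%d, gold n=%d); metrics set to 0",
            n_test, n_gold,
        )
    precision = tp / n_test if n_test else 0.0
    recall = tp / n_gold if n_gold else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return CohortComparison(
        n_gold=n_gold,
        n_test=n_test,
        tp=tp,
        fp=n_test - tp,
        fn=n_gold - tp,
        precision=precision,
        recall=recall,
        f1=f1,
        precision_ci=_wilson(tp, n_test),
        recall_ci=_wilson(tp, n_gold),
        f1_ci=None,
        metadata={"ci_method": "wilson", "alpha": 0.05},
    )


def compare_demographics(
    test: Cohort, gold: Cohort, demographics: pd.DataFrame
) -> CohortComparison:
    """Sex-proportion and mean-age differences between gold and test
    cohorts (oriented gold minus test).

    Sex: difference in proportion female, Wald 95% interval, two-sided
    pooled z test. Age (at the registration midpoint): Welch 95% interval
    and t test. When both cohorts are identical the differences are 0 and
    the tests are degenerate (p reported as 1).
    """
    demo = demographics.copy()
    demo["age"] = age_at_midpoint(demo)
    demo = demo.set_index("patient_id")

    def _subset(cohort: Cohort) -> pd.DataFrame:
        ids = sorted(cohort.patient_ids)
        missing = [i for i in ids if i not in demo.index]
        if missing:
            raise PhenokitError(
                f"no demographics row for patient {missing[0]}"
            )
        return demo.loc[ids]

    dg, dt = _subset(gold), _subset(test)
    n_g, n_t = len(dg), len(dt)
    x_g = int((dg["sex"] == "female").sum())
    x_t = int((dt["sex"] == "female").sum())
    p_g, p_t = x_g / n_g, x_t / n_t
    diff = p_g - p_t
    se = np.sqrt(p_g * (1 - p_g) / n_g + p_t * (1 - p_t) / n_t)
    z = stats.norm.ppf(0.975)
    sex_ci = (diff - z * se, diff + z * se)
    if se == 0:
        sex_p = 1.0 if diff == 0 else 0.0
    else:
        _, sex_p = proportions_ztest([x_g, x_t], [n_g, n_t])

    age_g = dg["age"].to_numpy(float)
    age_t = dt["age"].to_numpy(float)
    age_diff = float(age_g.mean() - age_t.mean())
    # constant samples (range exactly 0) make the t statistic undefined
    if np.ptp(age_g) == 0 and np.ptp(age_t) == 0:
        age_ci = (age_diff, age_diff)
        age_p = 1.0 if age_diff == 0 else 0.0
    else:
        res = stats.ttest_ind(age_g, age_t, equal_var=False)
        ci = res.confidence_interval(0.95)
        age_ci = (float(ci.low), float(ci.high))
        age_p = float(res.pvalue)

    return CohortComparison(
        n_gold=n_g,
        n_test=n_t,
        sex_proportion_diff=float(diff),
        sex_diff_ci=(float(sex_ci[0]), float(sex_ci[1])),
        sex_p=float(sex_p),
        mean_age_diff=age_diff,
        age_diff_ci=age_ci,
        age_p=age_p,
        metadata={
            "sex_ci_method": "wald",
            "sex_test": "two-sided pooled z",
            "age_ci_method": "welch",
            "age_test": "welch t",
            "orientation": "gold minus test",
        },
    )


def compare_cohorts(
    test: Cohort, gold: Cohort, demographics: Optional[pd.DataFrame] = None
) -> CohortComparison:
    """Full comparison: agreement metrics plus (when demographics are
    given) demographic differences, in one CohortComparison."""
    out = cohort_metrics(test, gold)
    if demographics is not None and len(test) and len(gold):
        demo = compare_demographics(test, gold, demographics)
        out.sex_proportion_diff = demo.sex_proportion_diff
        out.sex_diff_ci = demo.sex_diff_ci
        out.sex_p = demo.sex_p
        out.mean_age_diff = demo.mean_age_diff
        out.age_diff_ci = demo.age_diff_ci
        out.age_p = demo.age_p
        out.metadata.update(demo.metadata)
    return out
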