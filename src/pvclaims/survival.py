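"""Kaplan-Meier, log-rank and Cox comparison of co-exposure groups.

Subjects enter at their first index-drug prescription month; the event is
the first qualifying diagnosis at or after that month, and follow-up ends
at disenrolment.  Monthly claims produce heavily tied event times, so the
Cox model uses the Efron tie approximation (lifelines' default) and the
log-rank test its standard tied-event hypergeometric form.  An event in
the index month itself cannot be ordered within the month; it is assigned
time 0.5 so the interval has positive length.

Three-year cumulative incidence is reported both ways the field does:
as the Kaplan-Meier ``1 - S(36)`` (censoring-adjusted) and as the crude
proportion of cases among cohort members (the form printed in claims
baseline tables).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from pvclaims.claims import ClaimsPopulation, Cohort, CohortConfig, first_event_month

SAME_MONTH_TIME = 0.5  # months; within-month order is unobservable


def build_survival(
    cohort: Cohort,
    pop: ClaimsPopulation,
    config: CohortConfig | None = None,
    group_ids: set | None = None,
    group_name: str = "codrug",
) -> pd.DataFrame:
    """Per-subject (time, event, group) from cohort and claims tables.

    Time origin is the index month; events are first diagnoses at or after
    it (same-month events get time ``SAME_MONTH_TIME``); censoring is at
    enrolment end.  Patients whose first event precedes the index month
    carry prevalent disease and are excluded (counted in ``cohort.log``).
    ``group_ids`` marks the co-exposed group.
    """
    config = config or cohort.config
    members = cohort.members.set_index("patient_id")["index_month"]
    ev_first = first_event_month(pop, config.event_codes).reindex(members.index)
    enrol_end = pop.patients.set_index("patient_id")["enrol_end"].reindex(members.index)

    prevalent = ev_first < members
    n_prev = int(prevalent.fillna(False).sum())
    cohort.log["prevalent_event_excluded"] = n_prev
    keep = ~prevalent.fillna(False)

    idx = members.index[keep]
    m_d = members[keep]
    m_e = ev_first[keep]
    cens = (enrol_end[keep] - m_d).astype(float)
    has_event = m_e.notna() & (m_e - m_d <= cens)
    time = np.where(has_event, (m_e - m_d).astype(float), cens)
    time = np.where(has_event & (time == 0.0), SAME_MONTH_TIME, time)
    subjects = pd.DataFrame(
        {
            "patient_id": idx,
            "time": time,
            "event": has_event.to_numpy(bool),
            "group": [pid in group_ids for pid in idx] if group_ids is not None else False,
        }
    )
    subjects.attrs["group_name"] = group_name
    return subjects.reset_index(drop=True)


@dataclass
class KMCurve:
    """Product-limit survival on the monthly grid with at-risk counts."""

    label: str
    months: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    @property
    def incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months,
                "survival": self.survival,
                "incidence": self.incidence,
                "at_risk": self.at_risk,
                "group": self.label,
            }
        )


def km_estimate(subjects: pd.DataFrame, by_group: bool = True) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate per group on an integer monthly grid."""
    curves: dict[str, KMCurve] = {}
    groups = subjects.groupby("group") if by_group else [("all", subjects)]
    for label, grp in groups:
        if grp.empty:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        months = np.arange(0, int(math.ceil(grp["time"].max())) + 1)
        surv = kmf.survival_function_at_times(months).to_numpy()
        at_risk = np.array([(grp["time"] >= m).sum() for m in months])
        curves[str(label)] = KMCurve(str(label), months, surv, at_risk)
    return curves


def logrank(subjects: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-squared (1 df) and p-value."""
    g = subjects["group"].astype(bool)
    a, b = subjects[g], subjects[~g]
    if a.empty or b.empty:
        raise ValueError("log-rank test needs two non-empty groups")
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Single-binary-covariate proportional hazards fit (Efron ties)."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n_events: int
    monotone: bool = False  # zero events in one group: MLE on the boundary


def cox_hr(subjects: pd.DataFrame) -> CoxResult:
    """Hazard ratio of the co-exposure indicator from a Cox model.

    With zero events in one group the partial likelihood is monotone and
    the MLE sits at the boundary; a warning is raised and the CI reported
    as unbounded on the corresponding side.
    """
    g = subjects["group"].astype(bool)
    ev1 = int(subjects.loc[g, "event"].sum())
    ev0 = int(subjects.loc[~g, "event"].sum())
    if ev0 + ev1 == 0:
        raise ValueError("no events in either group")
    if ev0 == 0 or ev1 == 0:
        warnings.warn(
            "zero events in one group: monotone partial likelihood, "
            "hazard ratio on the boundary",
            RuntimeWarning,
            stacklevel=2,
        )
        hr = 0.0 if ev1 == 0 else math.inf
        return CoxResult(
            hr=hr,
            ci_low=0.0,
            ci_high=math.inf,
            wald_p=float("nan"),
            n_events=ev0 + ev1,
            monotone=True,
        )
    frame = pd.DataFrame(
        {
            "time": subjects["time"].astype(float),
            "event": subjects["event"].astype(int),
            "group": g.astype(int),
        }
    )
    cph = CoxPHFitter()
    # default Newton stopping leaves ~1e-4 slack on tiny data sets
    cph.fit(
        frame,
        duration_col="time",
        event_col="event",
        fit_options={"precision": 1e-9, "max_steps": 500},
    )
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return CoxResult(
        hr=math.exp(coef),
        ci_low=math.exp(coef - 1.959963984540054 * se),
        ci_high=math.exp(coef + 1.959963984540054 * se),
        wald_p=float(cph.summary.loc["group", "p"]),
        n_events=ev0 + ev1,
    )


def cumulative_incidence_at(curve: KMCurve, horizon: int = 36) -> tuple[float, bool]:
    """KM cumulative incidence (percent) at a month horizon.

    Beyond the last observed month the last available value is returned
    with the truncation flag set.
    """
    if horizon > curve.months[-1]:
        return float(curve.incidence[-1] * 100.0), True
    i = int(np.searchsorted(curve.months, horizon))
    return float(curve.incidence[i] * 100.0), False


def crude_incidence(subjects: pd.DataFrame, horizon: int = 36) -> float:
    """Crude case proportion by the horizon (percent): cases / cohort size."""
    if subjects.empty:
        return 0.0
    cases = (subjects["event"] & (subjects["time"] <= horizon)).sum()
    return float(cases) / len(subjects) * 100.0
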