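"""Claims-cohort construction and sequence symmetry analysis (SSA).

Works on monthly insurance-claims tables: enrolment spans per patient,
prescriptions with route and daily dose, and ICD-10 coded diagnoses, all at
calendar-month resolution (integer month indices; exact dates are removed
from such data at de-identification).

The cohort pipeline mirrors a new-user design on monthly claims:

* ``apply_run_in`` drops patients whose apparently-first index prescription
  or first event diagnosis falls in the first months after enrolment, where
  prevalent use/disease carried over from before enrolment masquerades as
  incident;
* ``build_cohort`` keeps patients with at least one index prescription,
  optionally excluding those who only ever received the injectable route
  (short-term in-hospital use, not the long-term exposure of interest);
* ``sequence_symmetry`` compares, among patients with both a first index
  prescription and a first event within +/- ``window_months``, how often
  the drug precedes the event versus follows it.  The crude sequence ratio
  is corrected for calendar trends in prescribing and diagnosis by a
  null-effect sequence ratio computed from the marginal monthly counts:

      null_sr = [sum_t d_t * sum_{u=t+1..t+w} e_u]
              / [sum_t d_t * sum_{u=t-w..t-1} e_u]

  and the adjusted ratio is crude / null.  Same-month pairs cannot be
  ordered and are excluded from the counts and from the marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pvclaims.errors import InputError, NoPairsError

DEFAULT_EVENT_CODES = frozenset({"J704", "J841", "J849"})


@dataclass
class ClaimsPopulation:
    """Monthly claims tables sharing the patient_id key."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frame, cols in (
            ("patients", self.patients, ["patient_id", "enrol_start", "enrol_end"]),
            ("prescriptions", self.prescriptions, ["patient_id", "generic_id", "month"]),
            ("diagnoses", self.diagnoses, ["patient_id", "icd10", "month"]),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise InputError(f"{name} table lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.patients)

    def restrict(self, patient_ids: pd.Series | set, **log_updates: int) -> "ClaimsPopulation":
        keep = set(patient_ids)
        log = dict(self.log)
        log.update(log_updates)
        return ClaimsPopulation(
            self.patients[self.patients["patient_id"].isin(keep)].reset_index(drop=True),
            self.prescriptions[self.prescriptions["patient_id"].isin(keep)].reset_index(drop=True),
            self.diagnoses[self.diagnoses["patient_id"].isin(keep)].reset_index(drop=True),
            log,
        )


def load_claims(patients_path, prescriptions_path, diagnoses_path, delimiter: str = ",") -> ClaimsPopulation:
    frames = []
    for path in (patients_path, prescriptions_path, diagnoses_path):
        if not Path(path).exists():
            raise InputError(f"missing input table: {path}")
        frames.append(pd.read_csv(path, sep=delimiter))
    return ClaimsPopulation(*frames)


@dataclass
class CohortConfig:
    """Cohort and SSA settings for one index drug / event definition."""

    index_drug: str
    event_codes: frozenset[str] = DEFAULT_EVENT_CODES
    run_in_months: int = 3
    window_months: int = 36
    exclude_injection_only: bool = True

    def __post_init__(self) -> None:
        self.event_codes = frozenset(self.event_codes)
        if self.run_in_months < 0:
            raise InputError("run_in_months must be >= 0")
        if self.window_months <= 0:
            raise InputError("window_months must be > 0")


def first_index_month(pop: ClaimsPopulation, drug: str) -> pd.Series:
    """First prescription month of a drug per patient (patient_id index)."""
    rx = pop.prescriptions
    return rx.loc[rx["generic_id"] == drug].groupby("patient_id")["month"].min()


def first_event_month(pop: ClaimsPopulation, codes: frozenset[str]) -> pd.Series:
    """First diagnosis month over a code set per patient (patient_id index)."""
    dx = pop.diagnoses
    return dx.loc[dx["icd10"].isin(codes)].groupby("patient_id")["month"].min()


def apply_run_in(pop: ClaimsPopulation, config: CohortConfig) -> ClaimsPopulation:
    """Drop patients whose first index prescription or first event falls in
    the run-in window (months ``0 .. run_in_months-1`` after enrolment).

    Patients with neither the drug nor the event are retained.  Idempotent:
    survivors have first occurrences at offset >= run_in_months or never.
    """
    pat = pop.patients.set_index("patient_id")
    rx_first = first_index_month(pop, config.index_drug)
    ev_first = first_event_month(pop, config.event_codes)
    bad_rx = rx_first - pat["enrol_start"].reindex(rx_first.index) < config.run_in_months
    bad_ev = ev_first - pat["enrol_start"].reindex(ev_first.index) < config.run_in_months
    excluded = set(bad_rx[bad_rx].index) | set(bad_ev[bad_ev].index)
    keep = pop.patients.loc[~pop.patients["patient_id"].isin(excluded), "patient_id"]
    return pop.restrict(keep, run_in_excluded=len(excluded))


@dataclass
class Cohort:
    """Index-drug users with their index month (first prescription)."""

    members: pd.DataFrame  # patient_id, index_month
    config: CohortConfig
    log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def empty(self) -> bool:
        return len(self.members) == 0


def build_cohort(pop: ClaimsPopulation, config: CohortConfig) -> Cohort:
    """Members = patients with >= 1 index prescription; injectable-only
    users are excluded when the config says so.  Apply run-in first."""
    rx = pop.prescriptions
    idx_rx = rx[rx["generic_id"] == config.index_drug]
    first = idx_rx.groupby("patient_id")["month"].min()
    n_users = len(first)
    excluded_injection = 0
    if config.exclude_injection_only and "route" in rx.columns and n_users:
        all_inj = idx_rx.groupby("patient_id")["route"].agg(lambda r: (r == "injection").all())
        drop = set(all_inj[all_inj].index)
        excluded_injection = len(drop)
        first = first[~first.index.isin(drop)]
    members = first.rename("index_month").reset_index()
    log = {
        "index_users": n_users,
        "injection_only_excluded": excluded_injection,
        "cohort_size": len(members),
    }
    if members.empty:
        log["empty"] = 1
    return Cohort(members=members, config=config, log=log)


@dataclass
class SSAResult:
    """Crude, null-effect and adjusted sequence ratios with 95% CI."""

    n_pos: int          # drug then event
    n_neg: int          # event then drug
    n_same_month: int   # unordered, excluded
    crude_sr: float
    null_sr: float
    adjusted_sr: float
    ci_low: float
    ci_high: float


def _clopper_pearson(k: int, n: int) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return lo, hi


def _null_sequence_ratio(d_t: np.ndarray, e_t: np.ndarray, window: int) -> float:
    """Expected forward/backward pair ratio from the marginal month counts."""
    T = len(d_t)
    e_cum = np.concatenate([[0.0], np.cumsum(e_t)])  # e_cum[t] = sum e_0..e_{t-1}
    num = den = 0.0
    for t in range(T):
        hi = min(T, t + window + 1)
        lo = max(0, t - window)
        num += d_t[t] * (e_cum[hi] - e_cum[t + 1])    # u in (t, t+w]
        den += d_t[t] * (e_cum[t] - e_cum[lo])        # u in [t-w, t)
    if den == 0.0:
        return math.inf if num > 0 else math.nan
    return num / den


def sequence_symmetry(
    cohort: Cohort, pop: ClaimsPopulation, config: CohortConfig | None = None
) -> SSAResult:
    """Sequence symmetry analysis of index drug versus first event.

    ``pop`` must be the run-in-filtered population; marginal prescription
    counts come from the cohort's index months and marginal event counts
    from first events in the whole eligible population.  Same-month pairs
    are excluded from the pair counts and their patients from both
    marginals.  The adjusted-ratio CI divides the exact binomial CI on the
    crude ratio by the null-effect ratio (held fixed).
    """
    config = config or cohort.config
    w = config.window_months
    members = cohort.members.set_index("patient_id")["index_month"]
    ev_first = first_event_month(pop, config.event_codes)

    both = members.index.intersection(ev_first.index)
    delta = (ev_first.loc[both] - members.loc[both]).astype(int)
    same = delta.index[delta == 0]
    n_same = len(same)
    in_window = delta[(delta.abs() >= 1) & (delta.abs() <= w)]
    n_pos = int((in_window > 0).sum())
    n_neg = int((in_window < 0).sum())
    if n_pos + n_neg == 0:
        raise NoPairsError("no drug-event pairs inside the observation window")

    drop = set(same)
    d_months = members[~members.index.isin(drop)]
    e_months = ev_first[~ev_first.index.isin(drop)]
    t_max = int(
        max(
            d_months.max() if len(d_months) else 0,
            e_months.max() if len(e_months) else 0,
        )
    )
    d_t = np.bincount(d_months.astype(int), minlength=t_max + 1).astype(float)
    e_t = np.bincount(e_months.astype(int), minlength=t_max + 1).astype(float)
    null_sr = _null_sequence_ratio(d_t, e_t, w)

    crude = math.inf if n_neg == 0 else n_pos / n_neg
    adjusted = crude / null_sr if math.isfinite(crude) else math.inf
    p_lo, p_hi = _clopper_pearson(n_pos, n_pos + n_neg)
    sr_lo = p_lo / (1.0 - p_lo) if p_lo < 1.0 else math.inf
    sr_hi = p_hi / (1.0 - p_hi) if p_hi < 1.0 else math.inf
    return SSAResult(
        n_pos=n_pos,
        n_neg=n_neg,
        n_same_month=n_same,
        crude_sr=crude,
        null_sr=null_sr,
        adjusted_sr=adjusted,
        ci_low=sr_lo / null_sr,
        ci_high=sr_hi / null_sr if math.isfinite(sr_hi) else math.inf,
    )


def two_group_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """p-value comparing a binary characteristic between two groups.

    Yates-corrected chi-squared when all expected cells are >= 5, else
    Fisher's exact test — the standard mix for baseline tables.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.min() < 0:
        raise ValueError("negative cell in characteristics table")
    expected = stats.contingency.expected_freq(table) if table.sum() else np.zeros((2, 2))
    if table.sum() == 0:
        return float("nan")
    if (expected >= 5).all():
        return float(stats.chi2_contingency(table, correction=True)[1])
    return float(stats.fisher_exact(table)[1])


def split_by_codrug(
    cohort: Cohort,
    pop: ClaimsPopulation,
    codrug: str,
    conditions: dict[str, frozenset[str]] | None = None,
    drug_groups: dict[str, frozenset[str]] | None = None,
) -> tuple[Cohort, Cohort, pd.DataFrame]:
    """Split the cohort by any-time co-drug prescription (fixed groups).

    Membership in the co-exposed group requires >= 1 prescription of
    ``codrug`` anywhere in the record — a population-level split that
    accepts the immortal-time caveat.  Also emits a baseline
    characteristics table (age, sex, elderly fraction, plus optional
    ICD-10-coded conditions and drug groups) with chi-squared / Fisher
    p-values.
    """
    rx = pop.prescriptions
    cod_users = set(rx.loc[rx["generic_id"] == codrug, "patient_id"])
    is_cod = cohort.members["patient_id"].isin(cod_users)
    with_c = Cohort(cohort.members[is_cod].reset_index(drop=True), cohort.config)
    without_c = Cohort(cohort.members[~is_cod].reset_index(drop=True), cohort.config)

    pat = pop.patients.set_index("patient_id")
    rows: list[dict] = []
    ids_w = with_c.members["patient_id"]
    ids_wo = without_c.members["patient_id"]
    n_w, n_wo = len(ids_w), len(ids_wo)
    rows.append({"characteristic": "n", "without": n_wo, "with": n_w, "p": np.nan})

    if "age" in pat.columns:
        age_w = pat["age"].reindex(ids_w).dropna()
        age_wo = pat["age"].reindex(ids_wo).dropna()
        rows.append(
            {
                "characteristic": "median age (IQR)",
                "without": _median_iqr(age_wo),
                "with": _median_iqr(age_w),
                "p": np.nan,
            }
        )
        k_w, k_wo = int((age_w > 65).sum()), int((age_wo > 65).sum())
        rows.append(_binary_row("elderly (over 65)", k_wo, n_wo, k_w, n_w))
    if "sex" in pat.columns:
        k_w = int((pat["sex"].reindex(ids_w) == "M").sum())
        k_wo = int((pat["sex"].reindex(ids_wo) == "M").sum())
        rows.append(_binary_row("male", k_wo, n_wo, k_w, n_w))
    for label, codes in (conditions or {}).items():
        dx = pop.diagnoses
        have = set(dx.loc[dx["icd10"].isin(codes), "patient_id"])
        rows.append(
            _binary_row(
                label,
                int(ids_wo.isin(have).sum()),
                n_wo,
                int(ids_w.isin(have).sum()),
                n_w,
            )
        )
    for label, drugs in (drug_groups or {}).items():
        have = set(rx.loc[rx["generic_id"].isin(drugs), "patient_id"])
        rows.append(
            _binary_row(
                label,
                int(ids_wo.isin(have).sum()),
                n_wo,
                int(ids_w.isin(have).sum()),
                n_w,
            )
        )
    return without_c, with_c, pd.DataFrame(rows, columns=["characteristic", "without", "with", "p"])


def _median_iqr(x: pd.Series) -> str:
    if len(x) == 0:
        return "-"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _binary_row(label: str, k_wo: int, n_wo: int, k_w: int, n_w: int) -> dict:
    p = two_group_test(k_wo, n_wo, k_w, n_w) if min(n_wo, n_w) > 0 else np.nan
    return {
        "characteristic": label,
        "without": f"{k_wo} ({k_wo / n_wo:.1%})" if n_wo else "-",
        "with": f"{k_w} ({k_w / n_w:.1%})" if n_w else "-",
        "p": p,
    }


def exposure_summary(cohort: Cohort, pop: ClaimsPopulation, drug: str) -> pd.DataFrame:
    """Dose and duration summary for one drug over the cohort.

    Per patient: cumulative dose = sum(daily_dose x days_supplied); average
    daily dose = cumulative dose / total days supplied; administration
    period in days spans first to last prescription (monthly data carry no
    dispensing day, so the period is 30 x (last month - first month) plus
    the last prescription's days supplied).  Output: median, IQR and range
    per quantity; patients with missing dose fields are skipped and counted.
    """
    rx = pop.prescriptions
    members = set(cohort.members["patient_id"])
    rx = rx[(rx["generic_id"] == drug) & rx["patient_id"].isin(members)].copy()
    if rx.empty:
        return pd.DataFrame(
            columns=["quantity", "median", "q1", "q3", "min", "max", "n", "skipped"]
        )
    missing = rx["daily_dose_mg"].isna() | rx["days_supplied"].isna()
    skipped_ids = set(rx.loc[missing, "patient_id"])
    rx = rx[~rx["patient_id"].isin(skipped_ids)]
    per = rx.assign(dose=rx["daily_dose_mg"] * rx["days_supplied"]).groupby("patient_id")
    cumulative = per["dose"].sum()
    total_days = per["days_supplied"].sum()
    avg_daily = cumulative / total_days
    first_m, last_m = per["month"].min(), per["month"].max()
    last_days = rx.sort_values("month").groupby("patient_id")["days_supplied"].last()
    period = 30 * (last_m - first_m) + last_days
    rows = []
    for name, series in (
        ("average daily dose (mg)", avg_daily),
        ("cumulative dose (mg)", cumulative),
        ("administration period (day)", period),
    ):
        q1, med, q3 = np.percentile(series, [25, 50, 75])
        rows.append(
            {
                "quantity": name,
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": float(series.min()),
                "max": float(series.max()),
                "n": len(series),
                "skipped": len(skipped_ids),
            }
        )
    return pd.DataFrame(rows)
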