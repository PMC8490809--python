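"""Synthetic spontaneous-report and claims generators with known ground truth.

Two generators stand in for databases that cannot be redistributed:

``simulate_reports``
    Emits FAERS-style quarterly ASCII tables (DEMO / DRUG / REAC, "$"
    delimited) under a multiplicative risk model: each report lists drugs
    independently at per-drug background probabilities, and the probability
    of the target adverse event is the base rate times the association
    multiplier of every listed drug, times an interaction multiplier when a
    named drug pair is co-listed.  Duplicate reports are injected in the two
    flavours real FAERS cleaning must remove (a later case version of the
    same case, and an exact-profile copy under a new case id).

``simulate_claims``
    Emits monthly claims tables (patients / prescriptions / diagnoses) with
    per-patient enrolment spans, an index-drug start process (optionally
    calendar-trending, optionally contaminated by prevalent users whose
    first prescription lands just after enrolment), a first-event hazard
    that is multiplied by ``causal_multiplier`` after index start (with lag)
    and by ``codrug_multiplier`` while a co-drug is active, injectable-only
    index users, and background diagnosis noise.

Both return the emitted tables plus a ground-truth sidecar carrying the
generative parameters and per-unit latent state, so downstream estimators
have parameter-recovery oracles.  Identical config + seed gives identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pvclaims.errors import ConfigError

# Narrow-scope style event vocabulary: highly specific ILD terms only.
DEFAULT_EVENT_TERMS = (
    "interstitial lung disease",
    "pulmonary fibrosis",
    "pneumonitis",
    "alveolitis allergic",
)
# Background vocabulary sized like a preferred-term dictionary slice: with a
# small vocabulary, distinct reports collide on the exact-profile dedup key
# at unrealistic rates (real report dictionaries hold thousands of terms).
DEFAULT_BACKGROUND_TERMS = (
    "nausea",
    "headache",
    "dizziness",
    "rash",
    "fatigue",
    "diarrhoea",
    "insomnia",
    "pruritus",
    "vomiting",
    "pyrexia",
) + tuple(f"background term {i:03d}" for i in range(290))


@dataclass
class ReportSimConfig:
    """Generative model for a FAERS-like spontaneous report set.

    ``drug_catalog`` maps generic ids to background listing probabilities;
    ``association_multipliers`` are relative reporting ratios for the event
    given the drug (1 = no association); ``interaction_multiplier`` applies
    on top when both members of ``interaction_pair`` are co-listed.
    """

    n_reports: int
    drug_catalog: list[tuple[str, float]]
    aliases: dict[str, list[str]] = field(default_factory=dict)
    event_base_rate: float = 0.02
    association_multipliers: dict[str, float] = field(default_factory=dict)
    interaction_pair: tuple[str, str] | None = None
    interaction_multiplier: float = 1.0
    duplicate_rate: float = 0.0
    event_terms: tuple[str, ...] = DEFAULT_EVENT_TERMS
    background_terms: tuple[str, ...] = DEFAULT_BACKGROUND_TERMS
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if not self.drug_catalog:
            raise ConfigError("drug_catalog must not be empty")
        names = [g for g, _ in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ConfigError("drug_catalog ids must be unique")
        for g, p in self.drug_catalog:
            if not 0.0 < p < 1.0:
                raise ConfigError(f"background probability for {g} not in (0,1)")
        if not 0.0 < self.event_base_rate < 1.0:
            raise ConfigError("event_base_rate not in (0,1)")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigError("duplicate_rate not in [0,1)")
        for g, m in self.association_multipliers.items():
            if m < 0:
                raise ConfigError(f"association multiplier for {g} is negative")
            if g not in set(names):
                raise ConfigError(f"multiplier refers to unknown drug {g}")
        if self.interaction_multiplier < 0:
            raise ConfigError("interaction_multiplier is negative")
        if self.interaction_pair is not None:
            for g in self.interaction_pair:
                if g not in set(names):
                    raise ConfigError(f"interaction pair refers to unknown drug {g}")
        seen: dict[str, str] = {}
        for g, raws in self.aliases.items():
            for r in raws:
                key = r.strip().casefold()
                if key in seen and seen[key] != g:
                    raise ConfigError(f"alias {r!r} maps to two generic ids")
                seen[key] = g
        if not self.event_terms:
            raise ConfigError("event_terms must not be empty")


@dataclass
class ReportTables:
    """FAERS-like tables: DEMO, DRUG, REAC share the report_id key."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame

    def write(self, outdir, delimiter: str = "$") -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (("demo", self.demo), ("drug", self.drug), ("reac", self.reac)):
            p = outdir / f"{name}.txt"
            frame.to_csv(p, sep=delimiter, index=False)
            paths[name] = str(p)
        return paths


@dataclass
class ReportGroundTruth:
    """Generative parameters plus what the emitted tables hide."""

    config: ReportSimConfig
    n_unique: int                # distinct report profiles before duplication
    duplicate_report_ids: list[str]
    event_rate_observed: float   # event fraction among original reports

    def sidecar(self) -> pd.DataFrame:
        rows = [
            ("n_reports", self.config.n_reports),
            ("n_unique", self.n_unique),
            ("n_duplicates", len(self.duplicate_report_ids)),
            ("event_base_rate", self.config.event_base_rate),
            ("duplicate_rate", self.config.duplicate_rate),
            ("interaction_multiplier", self.config.interaction_multiplier),
            ("event_rate_observed", self.event_rate_observed),
            ("seed", self.config.seed),
        ]
        for g, m in sorted(self.config.association_multipliers.items()):
            rows.append((f"multiplier.{g}", m))
        return pd.DataFrame(rows, columns=["parameter", "value"])


def _alias_for(config: ReportSimConfig, rng: np.random.Generator, generic: str) -> str:
    raws = config.aliases.get(generic)
    if not raws:
        return generic.upper()
    return raws[int(rng.integers(len(raws)))]


def simulate_reports(config: ReportSimConfig) -> tuple[ReportTables, ReportGroundTruth]:
    """Draw a spontaneous report set under the multiplicative risk model.

    Returns the three delimited-ready tables and the ground truth.  Reports
    may list no catalog drug at all (they form the unexposed margin, as in
    real data where the drug of interest is simply absent).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    names = [g for g, _ in config.drug_catalog]
    probs = np.array([p for _, p in config.drug_catalog])
    k = len(names)

    exposed = rng.random((n, k)) < probs[None, :]

    log_mult = np.log(
        np.array(
            [max(config.association_multipliers.get(g, 1.0), 0.0) for g in names]
        ).clip(min=1e-300)
    )
    # zero multiplier -> log clipped but exp() underflows to 0 as intended
    p_event = config.event_base_rate * np.exp(exposed @ log_mult)
    for g, m in config.association_multipliers.items():
        if m == 0.0:
            p_event[exposed[:, names.index(g)]] = 0.0
    if config.interaction_pair is not None:
        i = names.index(config.interaction_pair[0])
        j = names.index(config.interaction_pair[1])
        both = exposed[:, i] & exposed[:, j]
        p_event[both] *= config.interaction_multiplier
    p_event = np.clip(p_event, 0.0, 0.99)
    event = rng.random(n) < p_event

    sex = np.where(rng.random(n) < 0.55, "F", "M")
    age = rng.integers(18, 91, n)

    # reaction term lists: event reports carry one narrow-scope term plus
    # background terms; non-event reports carry 2-5 distinct background
    # terms (reports listing several symptoms is the norm)
    ev_terms = np.array(config.event_terms, dtype=object)
    bg_terms = np.array(config.background_terms, dtype=object)
    term_pick = rng.integers(0, len(ev_terms), n)
    n_bg = np.minimum(2 + rng.poisson(1.0, n), 5)
    n_bg = np.where(event, np.minimum(n_bg - 1, 4), n_bg)  # event term counts too
    bg_draws = rng.integers(0, len(bg_terms), (n, 5))
    reactions: list[tuple[str, ...]] = []
    for idx in range(n):
        seen: list = []
        for j in bg_draws[idx, : n_bg[idx]]:
            t = bg_terms[j]
            if t not in seen:
                seen.append(t)
        if event[idx]:
            seen.insert(0, ev_terms[term_pick[idx]])
        reactions.append(tuple(seen))

    drugs_raw: list[tuple[str, ...]] = []
    for idx in range(n):
        listed = [names[j] for j in np.nonzero(exposed[idx])[0]]
        drugs_raw.append(tuple(_alias_for(config, rng, g) for g in listed))

    report_ids = [f"R{idx:08d}" for idx in range(n)]
    case_ids = [f"C{idx:08d}" for idx in range(n)]
    versions = np.ones(n, dtype=int)

    # ground-truth unique count: rule 1 removes every re-versioned row, rule 2
    # collapses identical (sex, age, drugs, reactions) profiles — including
    # coincidental collisions among originals, so count distinct profiles
    profiles = pd.Series(
        [
            (sex[idx], int(age[idx]), tuple(sorted(drugs_raw[idx])), tuple(sorted(reactions[idx])))
            for idx in range(n)
        ]
    )
    n_unique = int(profiles.nunique())

    dup_mask = rng.random(n) < config.duplicate_rate
    dup_src = np.nonzero(dup_mask)[0]
    dup_flavor = rng.random(len(dup_src)) < 0.5  # True -> higher case version

    all_rows = {
        "report_id": list(report_ids),
        "case_id": list(case_ids),
        "case_version": list(versions),
        "sex": list(sex),
        "age": [int(a) for a in age],
    }
    dup_ids: list[str] = []
    drugs_all = list(drugs_raw)
    reac_all = list(reactions)
    next_id = n
    for src, higher_version in zip(dup_src, dup_flavor):
        rid = f"R{next_id:08d}"
        dup_ids.append(rid)
        all_rows["report_id"].append(rid)
        if higher_version:
            all_rows["case_id"].append(case_ids[src])
            all_rows["case_version"].append(2)
        else:
            all_rows["case_id"].append(f"C{next_id:08d}")
            all_rows["case_version"].append(1)
        all_rows["sex"].append(sex[src])
        all_rows["age"].append(int(age[src]))
        drugs_all.append(drugs_raw[src])
        reac_all.append(reactions[src])
        next_id += 1

    demo = pd.DataFrame(all_rows)
    order = rng.permutation(len(demo))
    demo = demo.iloc[order].reset_index(drop=True)
    drugs_all = [drugs_all[i] for i in order]
    reac_all = [reac_all[i] for i in order]

    drug_rows = [
        (rid, raw, "PS" if j == 0 else "C")
        for rid, raws in zip(demo["report_id"], drugs_all)
        for j, raw in enumerate(raws)
    ]
    reac_rows = [
        (rid, term) for rid, terms in zip(demo["report_id"], reac_all) for term in terms
    ]
    drug = pd.DataFrame(drug_rows, columns=["report_id", "drug_name_raw", "role"])
    reac = pd.DataFrame(reac_rows, columns=["report_id", "event_term"])

    truth = ReportGroundTruth(
        config=config,
        n_unique=n_unique,
        duplicate_report_ids=dup_ids,
        event_rate_observed=float(event.mean()),
    )
    return ReportTables(demo=demo, drug=drug, reac=reac), truth


# ---------------------------------------------------------------------------
# claims


@dataclass
class ClaimsSimConfig:
    """Generative model for a monthly claims population.

    Calendar time is an integer month index ``0 .. observation_months-1``.
    Each patient is enrolled over a contiguous span; the index drug starts
    with per-month probability ``index_start_rate`` (scaled by
    ``1 + index_trend * t`` for calendar trend); the first-event hazard is
    ``event_base_hazard`` multiplied by ``causal_multiplier`` from
    ``causal_lag_months`` after index start onward and by
    ``codrug_multiplier`` from the co-drug start onward.
    ``runin_contamination`` is the probability that a patient carries a
    prevalent index prescription into months 0-2 after enrolment (a
    prevalent event diagnosis occurs at a quarter of that rate), emulating
    the spike of apparent first prescriptions just after insurance
    enrolment.
    """

    n_patients: int
    observation_months: int = 60
    min_enrolment_months: int = 12
    index_drug: str = "amiodarone"
    index_start_rate: float = 0.004
    index_trend: float = 0.0
    event_base_hazard: float = 0.001
    event_trend: float = 0.0
    causal_multiplier: float = 1.0
    causal_lag_months: int = 0
    codrug: str = "dabigatran"
    codrug_probability: float = 0.0
    codrug_multiplier: float = 1.0
    injection_only_fraction: float = 0.0
    runin_contamination: float = 0.10
    event_code_weights: dict[str, float] = field(
        default_factory=lambda: {"J849": 0.80, "J841": 0.14, "J704": 0.06}
    )
    background_dx_rate: float = 0.02
    background_codes: tuple[str, ...] = ("I10", "E11", "C349", "N189", "J00", "M545")
    therapy_stop_prob: float = 0.16
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.observation_months <= self.min_enrolment_months:
            raise ConfigError("observation_months must exceed min_enrolment_months")
        for name in (
            "index_start_rate",
            "event_base_hazard",
            "codrug_probability",
            "injection_only_fraction",
            "runin_contamination",
            "background_dx_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} not in [0,1]")
        if self.causal_multiplier < 0 or self.codrug_multiplier < 0:
            raise ConfigError("hazard multipliers must be >= 0")
        if self.causal_lag_months < 0:
            raise ConfigError("causal_lag_months must be >= 0")
        if abs(sum(self.event_code_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("event_code_weights must sum to 1")
        if not 0.0 < self.therapy_stop_prob <= 1.0:
            raise ConfigError("therapy_stop_prob not in (0,1]")


@dataclass
class ClaimsTables:
    """Monthly claims tables keyed by patient_id."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame

    def write(self, outdir, delimiter: str = ",") -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("patients", self.patients),
            ("prescriptions", self.prescriptions),
            ("diagnoses", self.diagnoses),
        ):
            p = outdir / f"{name}.csv"
            frame.to_csv(p, sep=delimiter, index=False)
            paths[name] = str(p)
        return paths


@dataclass
class ClaimsGroundTruth:
    """Per-patient latent state plus the generative parameters."""

    config: ClaimsSimConfig
    latent: pd.DataFrame  # patient_id, index_start, injection_only, codrug_user,
    #                       codrug_start, event_month, prevalent_rx, prevalent_dx

    def sidecar(self) -> pd.DataFrame:
        c = self.config
        rows = [
            ("n_patients", c.n_patients),
            ("observation_months", c.observation_months),
            ("index_start_rate", c.index_start_rate),
            ("event_base_hazard", c.event_base_hazard),
            ("causal_multiplier", c.causal_multiplier),
            ("causal_lag_months", c.causal_lag_months),
            ("codrug_probability", c.codrug_probability),
            ("codrug_multiplier", c.codrug_multiplier),
            ("injection_only_fraction", c.injection_only_fraction),
            ("runin_contamination", c.runin_contamination),
            ("seed", c.seed),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def _first_true(mask: np.ndarray) -> np.ndarray:
    """Row-wise index of first True, -1 where absent."""
    any_true = mask.any(axis=1)
    first = mask.argmax(axis=1)
    return np.where(any_true, first, -1)


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenation of arange(c) for each c in counts."""
    total = int(counts.sum())
    out = np.arange(total)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    return out - offsets


def simulate_claims(config: ClaimsSimConfig) -> tuple[ClaimsTables, ClaimsGroundTruth]:
    """Draw a monthly claims population with a lagged causal drug-event hazard."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_patients, config.observation_months

    start = rng.integers(0, T - config.min_enrolment_months, n)
    dur = rng.integers(config.min_enrolment_months, T + 1, n)
    end = np.minimum(start + dur, T - 1)

    t = np.arange(T)
    active = (t[None, :] >= start[:, None]) & (t[None, :] <= end[:, None])

    rate_t = np.clip(config.index_start_rate * (1.0 + config.index_trend * t), 0.0, 1.0)
    first_rx = _first_true(active & (rng.random((n, T)) < rate_t[None, :]))

    prevalent_rx = rng.random(n) < config.runin_contamination
    prev_rx_month = start + rng.integers(0, 3, n)
    first_rx = np.where(
        prevalent_rx,
        np.minimum(np.where(first_rx < 0, T, first_rx), prev_rx_month),
        first_rx,
    )

    is_user = first_rx >= 0
    injection_only = is_user & (rng.random(n) < config.injection_only_fraction)

    haz = np.where(active, config.event_base_hazard * (1.0 + config.event_trend * t)[None, :], 0.0)
    after_rx = is_user[:, None] & (t[None, :] >= (first_rx + config.causal_lag_months)[:, None])
    haz = np.where(after_rx, haz * config.causal_multiplier, haz)

    # co-drug users who also take the index drug start it near the index
    # month (same indication, co-managed); other users start uniformly
    codrug_user = rng.random(n) < config.codrug_probability
    codrug_start = start + (rng.random(n) * (end - start + 1)).astype(int)
    near_index = np.clip(first_rx + rng.integers(-2, 3, n), start, end)
    codrug_start = np.where(is_user, near_index, codrug_start)
    codrug_active = codrug_user[:, None] & (t[None, :] >= codrug_start[:, None])
    haz = np.where(codrug_active, haz * config.codrug_multiplier, haz)
    haz = np.clip(haz, 0.0, 1.0)

    event_month = _first_true(rng.random((n, T)) < haz)

    prevalent_dx = rng.random(n) < config.runin_contamination / 4.0
    prev_dx_month = start + rng.integers(0, 3, n)
    event_month = np.where(
        prevalent_dx,
        np.minimum(np.where(event_month < 0, T, event_month), prev_dx_month),
        event_month,
    )

    sex = np.where(rng.random(n) < 0.6, "M", "F")
    age = rng.integers(20, 75, n)
    pid = np.array([f"P{idx:07d}" for idx in range(n)])

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "enrol_start": start,
            "enrol_end": end,
            "sex": sex,
            "age": age,
        }
    )

    # index-drug prescriptions: monthly refills from first_rx for a geometric
    # therapy duration, truncated at enrolment end
    def _refill_rows(sel, start_m, length, drug, route, dose):
        first = start_m[sel]
        last = np.minimum(first + length[sel] - 1, end[sel])
        count = np.maximum(last - first + 1, 1)
        months = np.repeat(first, count) + _ragged_arange(count)
        return pd.DataFrame(
            {
                "patient_id": np.repeat(pid[sel], count),
                "generic_id": drug,
                "month": months,
                "route": np.repeat(route[sel], count) if route.ndim else route,
                "daily_dose_mg": np.repeat(dose[sel], count),
                "days_supplied": 30,
            }
        )

    ther_dur = rng.geometric(config.therapy_stop_prob, n)
    daily_dose = np.round(rng.lognormal(np.log(150.0), 0.35, n) / 5.0) * 5.0
    cod_dur = rng.geometric(min(config.therapy_stop_prob / 1.5, 1.0), n)
    cod_dose = rng.choice([220.0, 300.0], n)
    route_arr = np.where(injection_only, "injection", "oral")
    frames = []
    if is_user.any():
        frames.append(
            _refill_rows(np.nonzero(is_user)[0], first_rx, ther_dur, config.index_drug, route_arr, daily_dose)
        )
    if codrug_user.any():
        frames.append(
            _refill_rows(
                np.nonzero(codrug_user)[0], codrug_start, cod_dur, config.codrug,
                np.array("oral"), cod_dose,
            )
        )
    if frames:
        prescriptions = pd.concat(frames, ignore_index=True)
    else:
        prescriptions = pd.DataFrame(
            columns=["patient_id", "generic_id", "month", "route", "daily_dose_mg", "days_supplied"]
        )

    dx_rows: list[tuple[str, str, int]] = []
    ev_codes = list(config.event_code_weights)
    ev_w = np.array([config.event_code_weights[c] for c in ev_codes])
    has_event = event_month >= 0
    code_pick = rng.choice(len(ev_codes), n, p=ev_w)
    for i in np.nonzero(has_event)[0]:
        dx_rows.append((pid[i], ev_codes[code_pick[i]], int(event_month[i])))
    if config.background_dx_rate > 0:
        noise = active & (rng.random((n, T)) < config.background_dx_rate)
        codes = np.array(config.background_codes, dtype=object)
        ii, tt = np.nonzero(noise)
        picks = rng.integers(0, len(codes), len(ii))
        dx_rows.extend((pid[i], codes[c], int(m)) for i, m, c in zip(ii, tt, picks))
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "icd10", "month"])
    diagnoses = diagnoses.sort_values(["patient_id", "month"], kind="stable").reset_index(drop=True)

    latent = pd.DataFrame(
        {
            "patient_id": pid,
            "index_start": first_rx,
            "injection_only": injection_only,
            "codrug_user": codrug_user,
            "codrug_start": np.where(codrug_user, codrug_start, -1),
            "event_month": event_month,
            "prevalent_rx": prevalent_rx,
            "prevalent_dx": prevalent_dx,
        }
    )
    truth = ClaimsGroundTruth(config=config, latent=latent)
    return ClaimsTables(patients, prescriptions, diagnoses), truth


# ---------------------------------------------------------------------------
# demo worlds: an amiodarone-like index drug with a strong event association
# and a dabigatran-like protective co-drug, over a background catalog

DEMO_CATALOG: list[tuple[str, float]] = [
    ("amiodarone", 0.050),
    ("dabigatran", 0.030),
    ("metformin", 0.060),
    ("aspirin", 0.080),
    ("furosemide", 0.050),
    ("metoprolol", 0.050),
    ("atorvastatin", 0.070),
    ("omeprazole", 0.060),
    ("levothyroxine", 0.040),
    ("warfarin", 0.030),
    ("lisinopril", 0.050),
    ("sertraline", 0.030),
]

DEMO_ALIASES: dict[str, list[str]] = {
    "amiodarone": ["CORDARONE", "amiodarone HCl", "PACERONE", "Amiodarone hydrochloride"],
    "dabigatran": ["PRADAXA", "dabigatran etexilate", "Dabigatran Etexilate Mesylate"],
    "aspirin": ["ASA", "acetylsalicylic acid"],
    "furosemide": ["LASIX"],
    "warfarin": ["COUMADIN"],
}


def demo_report_config(n_reports: int = 50_000, seed: int = 0, **overrides) -> ReportSimConfig:
    """Report-world defaults: index-drug multiplier 10, protective
    interaction 0.2 for the (index, co-drug) pair, 5% duplicate rate."""
    kwargs = dict(
        n_reports=n_reports,
        drug_catalog=list(DEMO_CATALOG),
        aliases={k: list(v) for k, v in DEMO_ALIASES.items()},
        event_base_rate=0.02,
        association_multipliers={"amiodarone": 10.0},
        interaction_pair=("amiodarone", "dabigatran"),
        interaction_multiplier=0.2,
        duplicate_rate=0.05,
        seed=seed,
    )
    kwargs.update(overrides)
    return ReportSimConfig(**kwargs)


def demo_claims_config(n_patients: int = 30_000, seed: int = 0, **overrides) -> ClaimsSimConfig:
    """Claims-world defaults: causal event-hazard multiplier 5 after index
    start, protective co-drug multiplier 0.4, 10% injectable-only users."""
    kwargs = dict(
        n_patients=n_patients,
        observation_months=72,
        index_start_rate=0.004,
        event_base_hazard=0.0008,
        causal_multiplier=5.0,
        causal_lag_months=1,
        codrug_probability=0.10,
        codrug_multiplier=0.4,
        injection_only_fraction=0.10,
        seed=seed,
    )
    kwargs.update(overrides)
    return ClaimsSimConfig(**kwargs)
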