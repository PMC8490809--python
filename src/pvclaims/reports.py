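"""Ingestion and cleaning of FAERS-like spontaneous report tables.

A report set is held as a single :class:`pandas.DataFrame` (one row per
submitted report version) wrapped in :class:`ReportSet`, with drug and
reaction lists stored as tuples.  Cleaning follows the auditable core of
published FAERS procedures:

1. within a case id, keep only the highest case version (later submissions
   supersede earlier ones);
2. across case ids, collapse reports identical on
   (sex, age, sorted raw drug names, sorted reaction terms) — the
   exact-profile duplicates that re-enter the database under new ids.

Raw drug names are mapped to generic ids by case-insensitive exact match
against an alias lexicon (no fuzzy matching), and reports are flagged for
the target adverse event by intersection with a flat term set emulating a
narrow-scope standardized MedDRA query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pvclaims.errors import ConfigError, InputError

REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "case_version",
    "sex",
    "age",
    "drugs_raw",
    "reactions",
    "drugs",
    "event",
]


@dataclass
class DrugLexicon:
    """Alias -> generic-id map with optional display names.

    Alias keys are stored casefolded and whitespace-trimmed; a raw name
    matches iff its trimmed casefold equals a key.
    """

    alias_map: dict[str, str]
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for alias, generic in self.alias_map.items():
            key = alias.strip().casefold()
            if key in folded and folded[key] != generic:
                raise ConfigError(f"alias {alias!r} maps to two generic ids")
            folded[key] = generic
        self.alias_map = folded

    def lookup(self, raw: str) -> str | None:
        return self.alias_map.get(raw.strip().casefold())

    @classmethod
    def from_tsv(cls, path) -> "DrugLexicon":
        frame = pd.read_csv(path, sep="\t", header=None, names=["alias", "generic_id"])
        return cls(dict(zip(frame["alias"].astype(str), frame["generic_id"].astype(str))))

    @classmethod
    def from_aliases(cls, aliases: dict[str, list[str]]) -> "DrugLexicon":
        """Invert a generic_id -> raw names map (generator convention).

        The generic id itself is always accepted as its own alias.
        """
        alias_map: dict[str, str] = {}
        for generic, raws in aliases.items():
            alias_map[generic] = generic
            for raw in raws:
                alias_map[raw] = generic
        return cls(alias_map)


@dataclass
class EventTermSet:
    """Flat set of event-term codes defining the adverse event of interest."""

    terms: frozenset[str]
    label: str = "interstitial lung disease (narrow)"

    def __post_init__(self) -> None:
        self.terms = frozenset(t.strip().casefold() for t in self.terms)
        if not self.terms:
            raise ConfigError("event term set is empty")

    @classmethod
    def from_file(cls, path, label: str | None = None) -> "EventTermSet":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(frozenset(ln for ln in lines if ln), label or Path(path).stem)


@dataclass
class ReportSet:
    """Spontaneous reports, one row per submitted report version."""

    frame: pd.DataFrame
    log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def copy_with(self, frame: pd.DataFrame, **log_updates: int) -> "ReportSet":
        log = dict(self.log)
        log.update(log_updates)
        return ReportSet(frame.reset_index(drop=True), log)


def _require_columns(frame: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise InputError(f"{name} table lacks columns {missing}")


def reports_from_frames(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> ReportSet:
    """Assemble one record per report_id from the three FAERS-like tables.

    Drug/reaction rows whose report_id has no demographics row are dropped
    and counted; reports without any reaction row are invalid and dropped.
    """
    _require_columns(demo, ["report_id", "case_id", "case_version"], "DEMO")
    _require_columns(drug, ["report_id", "drug_name_raw"], "DRUG")
    _require_columns(reac, ["report_id", "event_term"], "REAC")

    demo = demo.dropna(subset=["report_id"]).copy()
    known = set(demo["report_id"])

    drug = drug.dropna(subset=["report_id", "drug_name_raw"])
    reac = reac.dropna(subset=["report_id", "event_term"])
    orphan_drug = int((~drug["report_id"].isin(known)).sum())
    orphan_reac = int((~reac["report_id"].isin(known)).sum())
    drug = drug[drug["report_id"].isin(known)]
    reac = reac[reac["report_id"].isin(known)]

    drug_map = drug.groupby("report_id")["drug_name_raw"].agg(tuple)
    reac_map = reac.groupby("report_id")["event_term"].agg(tuple)

    frame = demo.set_index("report_id")
    frame["drugs_raw"] = drug_map
    frame["reactions"] = reac_map
    frame["drugs_raw"] = frame["drugs_raw"].apply(
        lambda v: v if isinstance(v, tuple) else ()
    )
    no_reac = frame["reactions"].isna()
    n_no_reac = int(no_reac.sum())
    frame = frame[~no_reac].reset_index()
    frame["case_version"] = frame["case_version"].astype(int)
    frame["drugs"] = [frozenset()] * len(frame)
    frame["event"] = pd.NA
    frame = frame[[c for c in REPORT_COLUMNS if c in frame.columns]]
    return ReportSet(
        frame.reset_index(drop=True),
        log={
            "orphan_drug_rows": orphan_drug,
            "orphan_reac_rows": orphan_reac,
            "reports_without_reactions": n_no_reac,
        },
    )


def load_reports(
    demo_path, drug_path, reac_path, delimiter: str = "$"
) -> ReportSet:
    """Read the three delimited tables (FAERS quarterly ASCII convention)."""
    frames = []
    for path in (demo_path, drug_path, reac_path):
        if not Path(path).exists():
            raise InputError(f"missing input table: {path}")
        frames.append(pd.read_csv(path, sep=delimiter))
    return reports_from_frames(*frames)


def deduplicate_reports(reports: ReportSet) -> ReportSet:
    """Remove re-submitted and exact-copy duplicate reports.

    Rule 1: within each case_id keep the highest case_version (report_id as
    deterministic tie-break).  Rule 2: collapse records identical on
    (sex, age, sorted drugs_raw, sorted reactions) to the one with the
    smallest report_id.  The result is independent of input row order and
    the operation is idempotent.
    """
    frame = reports.frame
    if frame.empty:
        return reports.copy_with(frame, dedup_removed=0)
    n0 = len(frame)
    frame = (
        frame.sort_values(["case_id", "case_version", "report_id"], kind="stable")
        .groupby("case_id", as_index=False, sort=False)
        .tail(1)
    )
    profile = pd.Series(
        list(
            zip(
                frame["sex"].fillna(""),
                frame["age"].fillna(-1),
                frame["drugs_raw"].apply(lambda t: tuple(sorted(t))),
                frame["reactions"].apply(lambda t: tuple(sorted(t))),
            )
        ),
        index=frame.index,
    )
    frame = frame.assign(_profile=profile)
    frame = (
        frame.sort_values("report_id", kind="stable")
        .groupby("_profile", as_index=False, sort=False)
        .head(1)
        .drop(columns="_profile")
        .sort_values("report_id", kind="stable")
    )
    return reports.copy_with(frame, dedup_removed=n0 - len(frame))


def map_drug_names(reports: ReportSet, lexicon: DrugLexicon) -> ReportSet:
    """Resolve raw drug names to generic ids; unmatched names are counted."""
    unmatched = 0
    drugs: list[frozenset[str]] = []
    cache: dict[str, str | None] = {}
    for raws in reports.frame["drugs_raw"]:
        generics = set()
        for raw in raws:
            if raw not in cache:
                cache[raw] = lexicon.lookup(raw)
            hit = cache[raw]
            if hit is None:
                unmatched += 1
            else:
                generics.add(hit)
        drugs.append(frozenset(generics))
    frame = reports.frame.assign(drugs=drugs)
    return reports.copy_with(frame, unmatched_drug_names=unmatched)


def label_event(reports: ReportSet, terms: EventTermSet) -> ReportSet:
    """Flag each report whose reactions intersect the event term set."""
    if not terms.terms:
        raise ConfigError("event term set is empty")
    flags = [
        any(t.strip().casefold() in terms.terms for t in reacs)
        for reacs in reports.frame["reactions"]
    ]
    frame = reports.frame.assign(event=flags)
    return reports.copy_with(frame)


def prepare_reports(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    lexicon: DrugLexicon,
    terms: EventTermSet,
) -> ReportSet:
    """Full cleaning chain: assemble, deduplicate, map, label."""
    rs = reports_from_frames(demo, drug, reac)
    rs = deduplicate_reports(rs)
    rs = map_drug_names(rs, lexicon)
    return label_event(rs, terms)
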