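"""Ingestion and cleaning: loading, deduplication, mapping, labelling."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvclaims import reports as rp
from pvclaims import simulate as sim
from pvclaims.errors import ConfigError, InputError


def make_report_set(rows):
    """rows: (report_id, case_id, version, sex, age, drugs_raw, reactions)."""
    demo = pd.DataFrame(
        [r[:5] for r in rows],
        columns=["report_id", "case_id", "case_version", "sex", "age"],
    )
    drug = pd.DataFrame(
        [(r[0], d, "PS") for r in rows for d in r[5]],
        columns=["report_id", "drug_name_raw", "role"],
    )
    reac = pd.DataFrame(
        [(r[0], t) for r in rows for t in r[6]],
        columns=["report_id", "event_term"],
    )
    return rp.reports_from_frames(demo, drug, reac)


LEXICON = rp.DrugLexicon(
    {"CORDARONE": "amiodarone", "amiodarone HCl": "amiodarone", "PRADAXA": "dabigatran"}
)
TERMS = rp.EventTermSet(frozenset({"interstitial lung disease", "pneumonitis"}))


class TestLoad:
    def test_three_row_fixture_round_trip(self, tmp_path):
        rows = [
            ("R1", "C1", 1, "M", 60, ("CORDARONE",), ("pneumonitis",)),
            ("R2", "C2", 1, "F", 55, ("PRADAXA",), ("nausea",)),
            ("R3", "C3", 1, "F", 40, (), ("rash", "nausea")),
        ]
        demo = pd.DataFrame(
            [r[:5] for r in rows],
            columns=["report_id", "case_id", "case_version", "sex", "age"],
        )
        drug = pd.DataFrame(
            [(r[0], d, "PS") for r in rows for d in r[5]],
            columns=["report_id", "drug_name_raw", "role"],
        )
        reac = pd.DataFrame(
            [(r[0], t) for r in rows for t in r[6]],
            columns=["report_id", "event_term"],
        )
        for name, frame in (("demo", demo), ("drug", drug), ("reac", reac)):
            frame.to_csv(tmp_path / f"{name}.txt", sep="$", index=False)
        loaded = rp.load_reports(
            tmp_path / "demo.txt", tmp_path / "drug.txt", tmp_path / "reac.txt"
        )
        assert len(loaded) == 3
        assert loaded.log["orphan_drug_rows"] == 0

    def test_orphan_drug_row_dropped_and_counted(self):
        demo = pd.DataFrame(
            [("R1", "C1", 1, "M", 60)],
            columns=["report_id", "case_id", "case_version", "sex", "age"],
        )
        drug = pd.DataFrame(
            [("R1", "CORDARONE", "PS"), ("R9", "PRADAXA", "PS")],
            columns=["report_id", "drug_name_raw", "role"],
        )
        reac = pd.DataFrame([("R1", "nausea")], columns=["report_id", "event_term"])
        rs = rp.reports_from_frames(demo, drug, reac)
        assert len(rs) == 1
        assert rs.log["orphan_drug_rows"] == 1

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(InputError):
            rp.load_reports(tmp_path / "a", tmp_path / "b", tmp_path / "c")

    def test_missing_column_raises(self):
        with pytest.raises(InputError):
            rp.reports_from_frames(
                pd.DataFrame({"report_id": []}),
                pd.DataFrame({"report_id": [], "drug_name_raw": []}),
                pd.DataFrame({"report_id": [], "event_term": []}),
            )

    def test_synthetic_count_matches_generator(self):
        config = sim.demo_report_config(n_reports=3_000, seed=2, duplicate_rate=0.0)
        tables, _ = sim.simulate_reports(config)
        rs = rp.reports_from_frames(tables.demo, tables.drug, tables.reac)
        assert len(rs) == 3_000


class TestDeduplicate:
    def test_higher_case_version_wins(self):
        rs = make_report_set(
            [
                ("R1", "C1", 1, "M", 60, ("CORDARONE",), ("nausea",)),
                ("R2", "C1", 2, "M", 61, ("CORDARONE",), ("nausea", "rash")),
            ]
        )
        out = rp.deduplicate_reports(rs)
        assert list(out.frame["report_id"]) == ["R2"]

    def test_exact_profile_collapse_across_cases(self):
        rs = make_report_set(
            [
                ("R1", "C1", 1, "M", 60, ("a", "b"), ("nausea",)),
                ("R2", "C2", 1, "M", 60, ("b", "a"), ("nausea",)),
                ("R3", "C3", 1, "F", 60, ("b", "a"), ("nausea",)),
            ]
        )
        out = rp.deduplicate_reports(rs)
        assert len(out) == 2  # R1/R2 collapse (same profile), R3 differs on sex

    def test_order_independence(self):
        rows = [
            ("R1", "C1", 1, "M", 60, ("a",), ("x",)),
            ("R2", "C1", 2, "M", 60, ("a",), ("x", "y")),
            ("R3", "C3", 1, "F", 50, ("b",), ("z",)),
            ("R4", "C4", 1, "F", 50, ("b",), ("z",)),
        ]
        fwd = rp.deduplicate_reports(make_report_set(rows))
        rev = rp.deduplicate_reports(make_report_set(rows[::-1]))
        assert list(fwd.frame["report_id"]) == list(rev.frame["report_id"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5))
    def test_idempotence(self, seed, dup_rate):
        config = sim.demo_report_config(n_reports=150, seed=seed, duplicate_rate=dup_rate)
        tables, _ = sim.simulate_reports(config)
        rs = rp.reports_from_frames(tables.demo, tables.drug, tables.reac)
        once = rp.deduplicate_reports(rs)
        twice = rp.deduplicate_reports(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_empty_input(self):
        rs = make_report_set([])
        assert len(rp.deduplicate_reports(rs)) == 0


class TestMapDrugNames:
    def test_aliases_resolve_to_one_generic(self):
        rs = make_report_set(
            [("R1", "C1", 1, "M", 60, ("CORDARONE", "amiodarone HCl"), ("x",))]
        )
        out = rp.map_drug_names(rs, LEXICON)
        assert out.frame["drugs"].iloc[0] == frozenset({"amiodarone"})

    def test_matching_is_case_insensitive_and_trimmed(self):
        rs = make_report_set([("R1", "C1", 1, "M", 60, ("  cordarone ",), ("x",))])
        out = rp.map_drug_names(rs, LEXICON)
        assert out.frame["drugs"].iloc[0] == frozenset({"amiodarone"})

    def test_unmatched_preserved_and_counted(self):
        rs = make_report_set([("R1", "C1", 1, "M", 60, ("mystery drug",), ("x",))])
        out = rp.map_drug_names(rs, LEXICON)
        assert out.frame["drugs"].iloc[0] == frozenset()
        assert out.frame["drugs_raw"].iloc[0] == ("mystery drug",)
        assert out.log["unmatched_drug_names"] == 1

    def test_mapping_preserves_report_count(self, demo_world):
        rs, _ = demo_world
        assert rs.log["unmatched_drug_names"] == 0  # every generated alias resolves

    def test_conflicting_lexicon_rejected(self):
        with pytest.raises(ConfigError):
            rp.DrugLexicon({"X": "a", " x ": "b"})


class TestLabelEvent:
    def test_flag_set_only_on_term_intersection(self):
        rs = make_report_set(
            [
                ("R1", "C1", 1, "M", 60, (), ("pneumonitis", "nausea")),
                ("R2", "C2", 1, "F", 50, (), ("nausea",)),
            ]
        )
        out = rp.label_event(rs, TERMS)
        assert list(out.frame["event"]) == [True, False]

    def test_empty_term_set_rejected(self):
        with pytest.raises(ConfigError):
            rp.EventTermSet(frozenset())

    def test_monotone_in_term_set(self):
        rs = make_report_set(
            [
                ("R1", "C1", 1, "M", 60, (), ("pneumonitis",)),
                ("R2", "C2", 1, "F", 50, (), ("rash",)),
            ]
        )
        small = rp.label_event(rs, TERMS)
        large = rp.label_event(
            rs, rp.EventTermSet(TERMS.terms | {"rash"})
        )
        assert (
            small.frame["event"].astype(bool) <= large.frame["event"].astype(bool)
        ).all()
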