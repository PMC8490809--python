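"""Cohort construction, sequence symmetry analysis, baseline tables."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import toy_population
from pvclaims import claims as cl
from pvclaims import simulate as sim
from pvclaims.errors import NoPairsError

CONF = cl.CohortConfig(index_drug="amiodarone")


class TestRunIn:
    def test_first_prescription_in_run_in_excludes_patient(self):
        pop = toy_population(
            [("P1", 10, 40)], [("P1", "amiodarone", 11)], []
        )
        out = cl.apply_run_in(pop, CONF)
        assert len(out) == 0 and out.log["run_in_excluded"] == 1

    def test_event_free_drug_free_patient_retained(self):
        pop = toy_population([("P1", 0, 40)], [], [("P1", "I10", 1)])
        out = cl.apply_run_in(pop, CONF)
        assert len(out) == 1

    def test_five_patient_enumeration_oracle(self):
        # brute-force rule: exclude iff first rx or first event offset < 3
        pop = toy_population(
            [("P%d" % i, 10, 60) for i in range(1, 6)],
            [
                ("P1", "amiodarone", 11),   # offset 1 -> excluded
                ("P2", "amiodarone", 20),   # offset 10 -> ok
                ("P4", "amiodarone", 13),   # offset 3 -> ok (boundary)
            ],
            [
                ("P3", "J849", 12),         # offset 2 -> excluded
                ("P4", "J841", 30),
            ],
        )
        out = cl.apply_run_in(pop, CONF)
        assert sorted(out.patients["patient_id"]) == ["P2", "P4", "P5"]

    def test_idempotence(self, demo_claims):
        _, pop, config, _ = demo_claims
        again = cl.apply_run_in(pop, config)
        assert len(again) == len(pop)


class TestBuildCohort:
    def test_injection_only_user_excluded(self):
        pop = toy_population(
            [("P1", 0, 40), ("P2", 0, 40)],
            [
                ("P1", "amiodarone", 10, "injection", 150.0, 30),
                ("P2", "amiodarone", 10, "oral", 150.0, 30),
                ("P2", "amiodarone", 12, "injection", 150.0, 30),
            ],
            [],
        )
        cohort = cl.build_cohort(pop, CONF)
        assert list(cohort.members["patient_id"]) == ["P2"]
        assert cohort.members["index_month"].iloc[0] == 10
        assert cohort.log["injection_only_excluded"] == 1

    def test_empty_cohort_flagged_not_fatal(self):
        pop = toy_population([("P1", 0, 40)], [], [])
        cohort = cl.build_cohort(pop, CONF)
        assert cohort.empty and cohort.log["empty"] == 1


class TestSequenceSymmetry:
    def test_toy_counts_and_crude_ratio(self):
        # 3 drug->event, 1 event->drug, one same-month pair excluded
        rows_rx = [(f"P{i}", "amiodarone", 20) for i in range(6)]
        rows_dx = [
            ("P0", "J849", 25),
            ("P1", "J849", 30),
            ("P2", "J849", 22),
            ("P3", "J849", 15),
            ("P4", "J849", 20),
        ]
        pop = toy_population([(f"P{i}", 3, 60) for i in range(6)], rows_rx, rows_dx)
        cohort = cl.build_cohort(pop, CONF)
        res = cl.sequence_symmetry(cohort, pop, CONF)
        first_rx = {f"P{i}": 20 for i in range(6)}
        first_ev = {"P0": 25, "P1": 30, "P2": 22, "P3": 15, "P4": 20}
        assert (res.n_pos, res.n_neg, res.n_same_month) == oracles.brute_force_ssa_counts(
            first_rx, first_ev, 36
        )
        assert res.crude_sr == pytest.approx(3.0)

    def test_counts_match_brute_force_on_simulated_population(self):
        config = sim.ClaimsSimConfig(
            n_patients=8_000,
            index_start_rate=0.01,
            event_base_hazard=0.004,
            causal_multiplier=3.0,
            runin_contamination=0.05,
            seed=23,
        )
        tables, _ = sim.simulate_claims(config)
        pop = cl.ClaimsPopulation(tables.patients, tables.prescriptions, tables.diagnoses)
        pop = cl.apply_run_in(pop, CONF)
        cohort = cl.build_cohort(pop, CONF)
        res = cl.sequence_symmetry(cohort, pop, CONF)
        first_rx = dict(zip(cohort.members["patient_id"], cohort.members["index_month"]))
        ev = cl.first_event_month(pop, CONF.event_codes)
        n_pos, n_neg, n_same = oracles.brute_force_ssa_counts(
            first_rx, ev.to_dict(), CONF.window_months
        )
        assert (res.n_pos, res.n_neg, res.n_same_month) == (n_pos, n_neg, n_same)
        assert res.crude_sr == pytest.approx(n_pos / n_neg)

    def test_constant_marginals_give_null_ratio_one(self):
        d = np.full(120, 5.0)
        e = np.full(120, 3.0)
        assert cl._null_sequence_ratio(d, e, 36) == pytest.approx(1.0)

    def test_symmetric_toy_is_fully_null(self):
        # equal forward/backward pairs, flat marginals -> everything 1
        rx = [(f"P{i}", "amiodarone", 20 + i) for i in range(8)]
        dx = [(f"P{i}", "J849", 20 + i + (2 if i % 2 else -2)) for i in range(8)]
        pop = toy_population([(f"P{i}", 3, 60) for i in range(8)], rx, dx)
        cohort = cl.build_cohort(pop, CONF)
        res = cl.sequence_symmetry(cohort, pop, CONF)
        assert res.n_pos == res.n_neg == 4
        assert res.crude_sr == pytest.approx(1.0)

    def test_zero_backward_pairs_reports_infinite_ratio(self):
        pop = toy_population(
            [("P1", 3, 60), ("P2", 3, 60), ("P3", 3, 60)],
            [("P1", "amiodarone", 10), ("P2", "amiodarone", 10)],
            # P3 has an event but never the drug: keeps the backward
            # marginal window populated so the null ratio stays finite
            [("P1", "J849", 15), ("P2", "J849", 20), ("P3", "J849", 5)],
        )
        cohort = cl.build_cohort(pop, CONF)
        res = cl.sequence_symmetry(cohort, pop, CONF)
        assert math.isinf(res.adjusted_sr) and math.isinf(res.ci_high)
        assert res.ci_low > 0

    def test_no_pairs_raises(self):
        pop = toy_population(
            [("P1", 3, 60)], [("P1", "amiodarone", 10)], []
        )
        cohort = cl.build_cohort(pop, CONF)
        with pytest.raises(NoPairsError):
            cl.sequence_symmetry(cohort, pop, CONF)

    def test_causal_world_recovery_against_scaled_up_oracle(self):
        # oracle value: the same generative process at 10x the size
        def adjusted(n, seed):
            config = sim.ClaimsSimConfig(
                n_patients=n,
                index_start_rate=0.01,
                event_base_hazard=0.002,
                causal_multiplier=5.0,
                runin_contamination=0.05,
                seed=seed,
            )
            tables, _ = sim.simulate_claims(config)
            pop = cl.ClaimsPopulation(
                tables.patients, tables.prescriptions, tables.diagnoses
            )
            pop = cl.apply_run_in(pop, CONF)
            res = cl.sequence_symmetry(cl.build_cohort(pop, CONF), pop, CONF)
            return res

        small = adjusted(50_000, seed=31)
        big = adjusted(500_000, seed=32)
        assert small.ci_low > 1.0
        assert abs(small.adjusted_sr - big.adjusted_sr) / big.adjusted_sr < 0.30


class TestSplitAndSummaries:
    def test_absent_codrug_gives_empty_group(self, demo_claims):
        cohort, pop, _, _ = demo_claims
        without_c, with_c, _ = cl.split_by_codrug(cohort, pop, "no-such-drug")
        assert len(with_c) == 0 and len(without_c) == len(cohort)

    def test_codrug_fraction_recovered(self, demo_claims):
        cohort, pop, _, truth = demo_claims
        p = truth.config.codrug_probability
        _, with_c, _ = cl.split_by_codrug(cohort, pop, "dabigatran")
        frac = len(with_c) / len(cohort)
        se = np.sqrt(p * (1 - p) / len(cohort))
        assert abs(frac - p) < 3 * se

    def test_published_sex_table_p_value(self):
        # male 1365/1674 vs 181/206, printed p = 0.03
        assert cl.two_group_test(1365, 1674, 181, 206) == pytest.approx(0.032, abs=0.002)

    def test_characteristics_table_shape(self, demo_claims):
        cohort, pop, _, _ = demo_claims
        _, _, chars = cl.split_by_codrug(
            cohort,
            pop,
            "dabigatran",
            conditions={"hypertension": frozenset({"I10"})},
            drug_groups={"warfarin use": frozenset({"warfarin"})},
        )
        assert list(chars.columns) == ["characteristic", "without", "with", "p"]
        assert {"n", "male", "hypertension", "warfarin use"} <= set(
            chars["characteristic"]
        )

    def test_exposure_summary_hand_arithmetic(self):
        pop = toy_population(
            [("P1", 0, 40), ("P2", 0, 40)],
            [
                ("P1", "amiodarone", 10, "oral", 100.0, 30),
                ("P2", "amiodarone", 10, "oral", 100.0, 30),
                ("P2", "amiodarone", 11, "oral", 200.0, 30),
            ],
            [],
        )
        cohort = cl.build_cohort(pop, CONF)
        out = cl.exposure_summary(cohort, pop, "amiodarone").set_index("quantity")
        # P1: avg 100, cum 3000, 30 days; P2: avg 150, cum 9000, 60 days
        assert out.loc["average daily dose (mg)", "min"] == 100.0
        assert out.loc["average daily dose (mg)", "max"] == 150.0
        assert out.loc["cumulative dose (mg)", "max"] == 9000.0
        assert out.loc["administration period (day)", "min"] == 30.0
        assert out.loc["administration period (day)", "max"] == 60.0

    def test_missing_dose_patient_skipped(self):
        pop = toy_population(
            [("P1", 0, 40), ("P2", 0, 40)],
            [
                ("P1", "amiodarone", 10, "oral", float("nan"), 30),
                ("P2", "amiodarone", 10, "oral", 100.0, 30),
            ],
            [],
        )
        cohort = cl.build_cohort(pop, CONF)
        out = cl.exposure_summary(cohort, pop, "amiodarone")
        assert (out["n"] == 1).all() and (out["skipped"] == 1).all()

    def test_empty_group_summary_no_crash(self):
        pop = toy_population([("P1", 0, 40)], [], [])
        cohort = cl.build_cohort(pop, CONF)
        assert cl.exposure_summary(cohort, pop, "amiodarone").empty
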