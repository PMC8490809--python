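import pandas as pd
import pytest

from pvclaims import claims as cl
from pvclaims import reports as rp
from pvclaims import simulate as sim


def prepare_world(config: sim.ReportSimConfig):
    """Simulate a report world and run the full cleaning chain on it."""
    tables, truth = sim.simulate_reports(config)
    lexicon = rp.DrugLexicon.from_aliases(config.aliases)
    for g, _ in config.drug_catalog:
        lexicon.alias_map.setdefault(g, g)
    terms = rp.EventTermSet(frozenset(config.event_terms))
    rs = rp.prepare_reports(tables.demo, tables.drug, tables.reac, lexicon, terms)
    return rs, truth


@pytest.fixture(scope="session")
def demo_world():
    """50k-report world: index-drug multiplier 10, protective interaction 0.2."""
    return prepare_world(sim.demo_report_config(n_reports=50_000, seed=11))


@pytest.fixture(scope="session")
def null_world():
    """60-drug world with every multiplier at 1: the independence null."""
    catalog = [(f"drug{i:02d}", 0.02 + 0.0005 * i) for i in range(60)]
    config = sim.ReportSimConfig(
        n_reports=50_000,
        drug_catalog=catalog,
        event_base_rate=0.02,
        duplicate_rate=0.0,
        seed=7,
    )
    return prepare_world(config)


@pytest.fixture(scope="session")
def demo_claims():
    """30k-patient claims world with causal multiplier 5 and protective co-drug."""
    tables, truth = sim.simulate_claims(sim.demo_claims_config(n_patients=30_000, seed=5))
    pop = cl.ClaimsPopulation(tables.patients, tables.prescriptions, tables.diagnoses)
    config = cl.CohortConfig(index_drug="amiodarone")
    pop = cl.apply_run_in(pop, config)
    cohort = cl.build_cohort(pop, config)
    return cohort, pop, config, truth


def toy_population(patients, prescriptions, diagnoses) -> cl.ClaimsPopulation:
    """Build a ClaimsPopulation from row tuples.

    patients: (pid, start, end[, sex, age]); prescriptions:
    (pid, drug, month[, route, dose, days]); diagnoses: (pid, code, month).
    """
    pat = pd.DataFrame(
        [tuple(p) + ("M", 50)[len(p) - 3 :] for p in patients],
        columns=["patient_id", "enrol_start", "enrol_end", "sex", "age"],
    )
    rx_rows = []
    for r in prescriptions:
        r = tuple(r) + ("oral", 100.0, 30)[len(r) - 3 :]
        rx_rows.append(r)
    rx = pd.DataFrame(
        rx_rows,
        columns=["patient_id", "generic_id", "month", "route", "daily_dose_mg", "days_supplied"],
    )
    dx = pd.DataFrame(diagnoses, columns=["patient_id", "icd10", "month"])
    return cl.ClaimsPopulation(pat, rx, dx)
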