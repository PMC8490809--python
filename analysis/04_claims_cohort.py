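#!/usr/bin/env python
"""Build the index-drug claims cohort and run sequence symmetry analysis.

Applies the run-in filter (first prescription or diagnosis in months 0-2
after enrolment excludes the patient), drops injectable-only users, then
tests temporal asymmetry between drug start and first event over a +/-36
month window, correcting the crude sequence ratio for calendar trends.
Also writes the baseline characteristics and dose/duration summaries for
the co-drug split.
"""

from pathlib import Path

import pandas as pd

from pvclaims import claims as cl

DATA = Path("results/data/claims")
OUT = Path("results/analysis")
CONFIG = cl.CohortConfig(index_drug="amiodarone")
CODRUG = "dabigatran"


def build() -> tuple[cl.Cohort, cl.ClaimsPopulation]:
    pop = cl.load_claims(DATA / "patients.csv", DATA / "prescriptions.csv", DATA / "diagnoses.csv")
    n0 = len(pop)
    pop = cl.apply_run_in(pop, CONFIG)
    cohort = cl.build_cohort(pop, CONFIG)
    print(f"{n0:,} patients -> {len(pop):,} after run-in "
          f"({pop.log['run_in_excluded']:,} excluded); cohort {len(cohort):,} "
          f"({cohort.log['injection_only_excluded']:,} injectable-only excluded)")
    return cohort, pop


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, pop = build()

    ssa = cl.sequence_symmetry(cohort, pop, CONFIG)
    pd.DataFrame([vars(ssa)]).to_csv(OUT / "ssa.csv", index=False)
    print(f"SSA: {ssa.n_pos} drug->event vs {ssa.n_neg} event->drug pairs "
          f"({ssa.n_same_month} same-month excluded); crude SR {ssa.crude_sr:.2f}, "
          f"null-effect SR {ssa.null_sr:.3f}, adjusted SR {ssa.adjusted_sr:.2f} "
          f"(95% CI {ssa.ci_low:.2f}-{ssa.ci_high:.2f})")

    without_c, with_c, chars = cl.split_by_codrug(
        cohort, pop, CODRUG,
        conditions={"hypertension": frozenset({"I10"}),
                    "diabetes mellitus": frozenset({"E11"}),
                    "lung cancer": frozenset({"C349"}),
                    "renal dysfunction": frozenset({"N189"})},
        drug_groups={"warfarin": frozenset({"warfarin"})},
    )
    chars.to_csv(OUT / "population_characteristics.csv", index=False)
    print(f"co-drug split: {len(without_c):,} without / {len(with_c):,} with {CODRUG}")

    for drug in (CONFIG.index_drug, CODRUG):
        cl.exposure_summary(cohort, pop, drug).to_csv(
            OUT / f"exposure_{drug}.csv", index=False
        )
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
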