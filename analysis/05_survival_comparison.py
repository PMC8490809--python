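#!/usr/bin/env python
"""Compare cumulative event incidence between co-drug groups.

From the cohort of 04_claims_cohort.py: Kaplan-Meier curves with at-risk
counts per group, the log-rank test, the Cox hazard ratio for the co-drug
indicator, and the 3-year incidence both censoring-adjusted (1 - S(36))
and as the crude case proportion.
"""

import runpy
from pathlib import Path

import pandas as pd

from pvclaims import claims as cl
from pvclaims import survival as sv

OUT = Path("results/analysis")
CODRUG = "dabigatran"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mod = runpy.run_path("analysis/04_claims_cohort.py")
    cohort, pop = mod["build"]()
    config = mod["CONFIG"]

    _, with_c, _ = cl.split_by_codrug(cohort, pop, CODRUG)
    subjects = sv.build_survival(
        cohort, pop, config, group_ids=set(with_c.members["patient_id"])
    )
    curves = sv.km_estimate(subjects)
    pd.concat([c.to_frame() for c in curves.values()], ignore_index=True).to_csv(
        OUT / "km_curves.csv", index=False
    )

    chi2, p = sv.logrank(subjects)
    cox = sv.cox_hr(subjects)
    rows = []
    for label, curve in curves.items():
        grp = subjects[subjects["group"] == (label == "True")]
        km36, _ = sv.cumulative_incidence_at(curve, 36)
        rows.append({
            "group": f"with {CODRUG}" if label == "True" else f"without {CODRUG}",
            "n": len(grp),
            "events": int(grp["event"].sum()),
            "km_incidence_36m_pct": round(km36, 2),
            "crude_incidence_36m_pct": round(sv.crude_incidence(grp, 36), 2),
        })
    summary = pd.DataFrame(rows)
    summary["logrank_chi2"], summary["logrank_p"] = chi2, p
    summary["hr"], summary["hr_ci_low"], summary["hr_ci_high"] = (
        cox.hr, cox.ci_low, cox.ci_high,
    )
    summary.to_csv(OUT / "survival_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"log-rank chi2 {chi2:.2f} (p {p:.2g}); Cox HR {cox.hr:.2f} "
          f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}, Wald p {cox.wald_p:.2g})")


if __name__ == "__main__":
    main()
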