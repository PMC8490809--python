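#!/usr/bin/env python
"""Screen concomitant drugs inside the index-drug report stratum.

Restricts the cleaned reports to those listing the index drug and computes
each co-listed drug's nested ROR — the co-drug with the injected protective
interaction should sit below 1 with a CI excluding 1.  Also writes the
four-group (neither / index only / co-drug only / both) event proportions.
"""

import runpy
from pathlib import Path

from pvclaims import disproportionality as dp

OUT = Path("results/analysis")
INDEX, CODRUG = "amiodarone", "dabigatran"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mod = runpy.run_path("analysis/02_report_screen.py")
    rs = mod["load_clean_reports"]()

    inter = dp.interaction_scan(rs, INDEX, min_cases=3)
    inter.to_csv(OUT / "interaction_scan.csv", index=False)
    row = inter[inter["drug"] == CODRUG]
    if row.empty:
        print(f"{CODRUG}: below the case floor in the {INDEX} stratum")
    else:
        r = row.iloc[0]
        print(f"nested ROR for {CODRUG} within the {INDEX} stratum "
              f"(n={int(r['stratum_size']):,}): {r['ror']:.2f} "
              f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})")

    props = dp.report_proportions(rs, INDEX, CODRUG)
    props.to_csv(OUT / "report_proportions.csv", index=False)
    print(props.to_string(index=False))


if __name__ == "__main__":
    main()
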