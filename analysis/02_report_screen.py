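#!/usr/bin/env python
"""Clean the spontaneous reports and run the all-drug disproportionality
screen.

Reads the tables written by 01_simulate_data.py, applies the two-rule
deduplication, maps raw drug names through the alias lexicon, labels the
target event, and screens every drug (ROR, 95% CI, Z).  The index drug
should dominate the volcano ranking; drugs with no injected association
should scatter around ROR = 1.
"""

from pathlib import Path

from pvclaims import disproportionality as dp
from pvclaims import reports as rp
from pvclaims import simulate as sim

DATA = Path("results/data/reports")
OUT = Path("results/analysis")


def load_clean_reports() -> rp.ReportSet:
    rs = rp.load_reports(DATA / "demo.txt", DATA / "drug.txt", DATA / "reac.txt")
    n_raw = len(rs)
    rs = rp.deduplicate_reports(rs)
    lexicon = rp.DrugLexicon.from_aliases(sim.DEMO_ALIASES)
    for generic, _ in sim.DEMO_CATALOG:
        lexicon.alias_map.setdefault(generic, generic)
    rs = rp.map_drug_names(rs, lexicon)
    rs = rp.label_event(rs, rp.EventTermSet(frozenset(sim.DEFAULT_EVENT_TERMS)))
    print(f"{n_raw:,} submitted reports -> {len(rs):,} after deduplication "
          f"(removed {rs.log['dedup_removed']:,}; unmatched drug names "
          f"{rs.log['unmatched_drug_names']:,})")
    return rs


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rs = load_clean_reports()
    scan = dp.signal_scan(rs, min_cases=3, add_bh=True)
    scan.to_csv(OUT / "signal_scan.csv", index=False)
    top = scan.iloc[0]
    print(f"top signal: {top['drug']} ROR {top['ror']:.2f} "
          f"(95% CI {top['ci_low']:.2f}-{top['ci_high']:.2f}), Z {top['z']:.1f}, "
          f"{int(top['n_cases'])} cases")
    print(f"full table ({len(scan)} drugs) -> {OUT / 'signal_scan.csv'}")


if __name__ == "__main__":
    main()
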