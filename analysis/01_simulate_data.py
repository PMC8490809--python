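#!/usr/bin/env python
"""Generate the two synthetic worlds used by the downstream analyses.

World A (spontaneous reports): 200,000 FAERS-like reports where the index
anti-arrhythmic carries a 10x event-reporting multiplier for the
interstitial-lung-disease term set and the co-listed anticoagulant a
protective 0.2x interaction; 5% of reports are re-emitted as duplicates.

World B (claims): 100,000 insured patients with monthly records where the
index drug multiplies the first-event hazard by 5 (one-month lag), the
co-drug multiplies it by 0.4 while active, 10% of index users only ever
receive the injectable route, and prevalent users contaminate the first
enrolment months.

Writes the delimited tables plus ground-truth sidecars under results/data/.
"""

from pathlib import Path

from pvclaims import simulate as sim

OUT = Path("results/data")
SEED = 1


def main() -> None:
    report_config = sim.demo_report_config(n_reports=200_000, seed=SEED)
    tables, truth = sim.simulate_reports(report_config)
    paths = tables.write(OUT / "reports")
    truth.sidecar().to_csv(OUT / "reports" / "ground_truth.csv", index=False)
    print(f"reports: {len(tables.demo):,} rows ({len(truth.duplicate_report_ids):,} "
          f"injected duplicates, {truth.n_unique:,} unique) -> {paths['demo']}")

    claims_config = sim.demo_claims_config(n_patients=100_000, seed=SEED + 1)
    ctables, ctruth = sim.simulate_claims(claims_config)
    cpaths = ctables.write(OUT / "claims")
    ctruth.sidecar().to_csv(OUT / "claims" / "ground_truth.csv", index=False)
    n_users = int((ctruth.latent["index_start"] >= 0).sum())
    print(f"claims: {len(ctables.patients):,} patients, {n_users:,} index-drug users, "
          f"{len(ctables.prescriptions):,} prescription rows -> {cpaths['patients']}")


if __name__ == "__main__":
    main()
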