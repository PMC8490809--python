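# Methods notes

## Scope and design

The package implements a two-source pharmacovigilance workflow: (i)
disproportionality mining on spontaneous adverse-event reports, including
a nested drug-drug interaction screen, and (ii) a claims-cohort analysis
(run-in filtering, sequence symmetry analysis with null-effect correction,
Kaplan–Meier / log-rank / Cox comparison of co-exposure groups). Both
sources have synthetic generators with explicit generative parameters, so
every estimator has a parameter-recovery or enumeration oracle.

## Spontaneous-report model

Each report lists each catalog drug independently with its background
probability; the event probability is

    P(event | drugs) = base_rate × Π_d multiplier(d) × interaction (if both pair members listed)

clipped at 0.99. Under this model the population ROR of a drug is an
exact function of the catalog (enumerable over exposure patterns of the
other drugs); note the ROR converges to the *odds* ratio implied by the
multiplier, which exceeds the risk multiplier when the exposed event rate
is non-negligible (multiplier 10 on a 2% base rate gives a generative ROR
≈ 12.3, not 10).

Reports carry 2–5 reaction terms drawn from a ~300-term vocabulary.  The
vocabulary size is not cosmetic: the deduplication contract collapses
reports identical on (sex, age, drugs, reactions), and with a small
vocabulary *distinct* reports collide on that key at unrealistic rates
(real term dictionaries hold thousands of preferred terms). With the
shipped vocabulary, coincidental collisions are ≈0.06% at n = 200,000,
and the ground-truth sidecar counts them exactly, so dedup recovery tests
are exact rather than approximate.

Duplicates are injected in the two flavours the cleaning rules target:
a higher case version under the same case id, and an exact-profile copy
under a fresh case id. Alias noise replaces generic drug names with
trade-name/abbreviation spellings resolved by the lexicon.

Default world (used by the analysis drivers and acceptance checks):
12-drug catalog with listing probabilities 2–8%, event base rate 2%,
index-drug multiplier 10, protective interaction 0.2 for the (index,
co-drug) pair, duplicate rate 5%. The index and co-drug listing
probabilities (5% and 3%) are deliberately a few-fold above their FAERS
shares so that, at desk-scale report counts, the nested interaction
stratum carries enough cases — the real database is ~50× larger. No
reporting-bias mechanisms (Weber effect, stimulated reporting) are
modelled, so green tests establish estimator correctness under
independence-plus-multipliers, not robustness to reporting artefacts.

## Claims model

Integer calendar months over a configurable span (default 72). Per
patient: a uniform enrolment start and duration (≥12 months); an
index-drug start process with per-month probability (optionally
calendar-trending) and geometric therapy persistence (monthly refills,
stop probability 0.16 — median ≈ 4 months, matching reported amiodarone
administration periods of ~116 days); lognormal daily dose (median 150
mg, near the reported 165 mg). A configurable fraction of index users is
injectable-only. The first-event hazard is multiplied by
`causal_multiplier` from one month after index start (the lag reflects
that same-month causality is unobservable in monthly data) and by
`codrug_multiplier` while the co-drug is active. Co-drug users who also
take the index drug start it within ±2 months of the index month (the two
drugs share an indication and are co-managed); other co-drug users start
uniformly.

Run-in contamination: with probability 0.10 a patient carries a prevalent
index prescription into months 0–2 after enrolment (prevalent diagnosis
at a quarter of that rate), emulating the spike of apparent first
occurrences just after insurance enrolment that motivates the run-in
exclusion.

## Estimator conventions

- **ROR**: Woolf SE on ln ROR; Haldane–Anscombe +0.5 on all cells when any
  cell is zero (flagged `corrected`); an empty exposure margin is an error,
  not a corrected value. Scans default to a 3-case floor. Concomitance is
  co-listing on the same report (reports carry no time stamps); the drug
  "role" field is read but ignored — any listed drug counts as exposure.
- **Deduplication** is order-independent and idempotent: rule 1 keeps the
  highest case version per case id (report id as tie-break), rule 2 keeps
  the smallest report id per identical profile.
- **Run-in**: a patient is excluded iff the first index prescription or
  first event diagnosis occurs at offset < `run_in_months` from the
  enrolment month (offset 0 = enrolment month itself).
- **SSA**: window closed on both ends (1 ≤ |Δ| ≤ w); same-month pairs are
  excluded from numerator, denominator and both marginal count vectors.
  Marginals: d_t from the cohort's index months (post run-in and
  injection exclusion), e_t from first events in the whole run-in-filtered
  population. The adjusted-SR CI divides the Clopper–Pearson interval on
  the crude ratio by the null-effect ratio treated as fixed — simple and
  conservative. With constant marginals the null ratio is exactly 1
  (window truncation at the calendar edges cancels by symmetry). Zero
  backward pairs give an infinite ratio with a one-sided CI; zero pairs
  raise an error.
- **Survival**: origin = index month; events are first qualifying
  diagnoses at or after it; same-month events get time 0.5 month (monthly
  data cannot order within-month events; the SSA excludes such pairs, but
  survival needs a convention). Patients whose first event precedes the
  index month are excluded as prevalent cases and counted in the log.
  Censoring at enrolment end. Cox uses the Efron tie approximation with a
  tightened Newton stopping rule (1e-9; the library default leaves ~1e-4
  slack on small fixtures, visible against the grid-search oracle).
  Three-year incidence is emitted both as KM 1−S(36) and as the crude
  case proportion; published claims tables use the crude proportion.
- **Baseline tables**: Yates-corrected chi-squared for 2×2 comparisons
  when all expected cells ≥ 5, Fisher's exact otherwise (this combination
  reproduces the published sex-distribution p = 0.03).
- **Co-drug split** is any-time prescription (fixed groups). This accepts
  the immortal-time caveat and attenuates the measured hazard ratio
  toward 1 relative to the generative co-drug multiplier when co-drug
  start is far from index start; with the co-managed start convention the
  attenuation is modest (generative 0.4 → measured ≈ 0.45–0.57 in the
  shipped worlds).

## Calibrated two-arm recovery

`calibration.replicate_cox_hr` solves 1−(1−h)^36 = p per arm for the
constant monthly hazard reproducing a printed 3-year incidence, draws
geometric event months and uniform censoring months on 1..36, and
averages the per-replicate Cox HR. With arms 1,674 / 206 calibrated to
incidences 12.4% / 5.8%, the generative hazard ratio is 0.453; the
arithmetic mean of per-replicate HRs is slightly above it (≈0.46–0.48)
because the small arm sees only ~6 events per replicate and the HR
distribution is right-skewed. Replicates where an arm has no events
(<1%) are redrawn, as the partial-likelihood MLE does not exist there.

## Numerical and degenerate-input choices

- Seeds: a single `numpy` Generator per simulation; identical config +
  seed gives byte-identical tables (asserted in tests and via manifest
  hashes in the pipeline).
- Empty cohort / empty scan outputs are flagged, not fatal; empty report
  groups in the four-group proportion table carry NaN with an `empty`
  flag.
- Administration period on monthly data: 30 × (last − first prescription
  month) + the last prescription's days supplied, so a single 30-day
  script spans 30 days.

## Known limitations

- The report generator's independence of drug exposures means
  confounding-by-co-prescription patterns (beyond the explicit interaction
  pair) are absent; channeling bias cannot be studied.
- The claims generator has no re-enrolment gaps, no dose-response in the
  event hazard, and calendar trends enter only linearly.
- The SSA null-effect correction treats the null ratio as fixed in the CI;
  its sampling variability is ignored (conservative at the sizes used).
- No multiple-testing adjustment in the primary scan output (ranking is
  by |Z|, as is conventional for volcano screens); an optional
  Benjamini–Hochberg column is available.
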