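"""End-to-end pipeline driven by a single YAML configuration.

Stages: simulate (or load) spontaneous reports -> ingest/clean -> all-drug
signal scan -> nested interaction scan -> four-group report proportions;
simulate (or load) claims -> run-in filter -> cohort -> sequence symmetry
-> co-drug split -> exposure summary -> Kaplan-Meier / log-rank / Cox.
Every stage writes its table under the output directory and appends a
manifest entry (stage, row counts, content hash), so re-running the same
config reproduces identical manifests and each cohort-attrition number is
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from pvclaims import claims as cl
from pvclaims import disproportionality as dp
from pvclaims import reports as rp
from pvclaims import simulate as sim
from pvclaims import survival as sv
from pvclaims.errors import ConfigError

log = logging.getLogger("pvclaims")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.entries: list[dict] = []
        self.seed = seed

    def write_table(self, stage: str, frame: pd.DataFrame, rows_in: int | None = None) -> Path:
        path = self.outdir / f"{stage}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        self.entries.append(
            {
                "stage": stage,
                "rows_in": rows_in,
                "rows_out": len(frame),
                "sha256": _sha256(path),
            }
        )
        log.info("stage %s: %s rows -> %s", stage, rows_in, len(frame))
        return path

    def flush(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"seed": self.seed, "stages": self.entries}, indent=2))
        return path


def _report_stage(config: dict, seed: int, man: _Manifest) -> rp.ReportSet:
    rconf = config.get("reports", {})
    if "simulate" in rconf:
        simc = sim.demo_report_config(seed=seed, **rconf["simulate"])
        tables, truth = sim.simulate_reports(simc)
        man.write_table("reports_ground_truth", truth.sidecar())
        lexicon = rp.DrugLexicon.from_aliases(simc.aliases or {g: [] for g, _ in simc.drug_catalog})
        for g, _ in simc.drug_catalog:
            lexicon.alias_map.setdefault(g, g)
        terms = rp.EventTermSet(frozenset(simc.event_terms))
    elif "paths" in rconf:
        p = rconf["paths"]
        tables = rp.load_reports(p["demo"], p["drug"], p["reac"], p.get("delimiter", "$"))
        lexicon = rp.DrugLexicon.from_tsv(p["lexicon"])
        terms = rp.EventTermSet.from_file(p["terms"])
        # load_reports already returns a ReportSet; keep a uniform interface
        rs = tables
        rs = rp.deduplicate_reports(rs)
        rs = rp.map_drug_names(rs, lexicon)
        return rp.label_event(rs, terms)
    else:
        raise ConfigError("reports section needs either 'simulate' or 'paths'")
    rs = rp.reports_from_frames(tables.demo, tables.drug, tables.reac)
    n0 = len(rs)
    rs = rp.deduplicate_reports(rs)
    rs = rp.map_drug_names(rs, lexicon)
    rs = rp.label_event(rs, terms)
    log.info("reports: %d raw, %d after dedup (%s)", n0, len(rs), rs.log)
    return rs


def _claims_stage(config: dict, seed: int, man: _Manifest) -> cl.ClaimsPopulation:
    cconf = config.get("claims", {})
    if "simulate" in cconf:
        simc = sim.demo_claims_config(seed=seed + 1, **cconf["simulate"])
        tables, truth = sim.simulate_claims(simc)
        man.write_table("claims_ground_truth", truth.sidecar())
        return cl.ClaimsPopulation(tables.patients, tables.prescriptions, tables.diagnoses)
    if "paths" in cconf:
        p = cconf["paths"]
        return cl.load_claims(p["patients"], p["prescriptions"], p["diagnoses"])
    raise ConfigError("claims section needs either 'simulate' or 'paths'")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute every stage; returns paths and headline results.

    Deterministic: the output tables (and so the manifest hashes) are a
    pure function of the configuration, including its seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.get("analysis", {})
    index_drug = analysis.get("index_drug", "amiodarone")
    codrug = analysis.get("codrug", "dabigatran")
    min_cases = int(analysis.get("min_cases", 3))
    horizon = int(analysis.get("horizon_months", 36))

    man = _Manifest(outdir, seed)
    results: dict = {"outdir": str(outdir)}

    # --- spontaneous reports ------------------------------------------------
    rs = _report_stage(config, seed, man)
    scan = dp.signal_scan(rs, min_cases=min_cases)
    man.write_table("signal_scan", scan, rows_in=len(rs))
    inter = dp.interaction_scan(rs, index_drug, min_cases=min_cases)
    man.write_table("interaction_scan", inter, rows_in=len(rs))
    props = dp.report_proportions(rs, index_drug, codrug)
    man.write_table("report_proportions", props, rows_in=len(rs))
    results["signal_scan"] = scan
    results["interaction_scan"] = inter
    results["report_proportions"] = props
    results["report_log"] = dict(rs.log)

    # --- claims cohort ------------------------------------------------------
    pop = _claims_stage(config, seed, man)
    cohort_conf = cl.CohortConfig(
        index_drug=index_drug,
        event_codes=frozenset(analysis.get("event_codes", cl.DEFAULT_EVENT_CODES)),
        run_in_months=int(analysis.get("run_in_months", 3)),
        window_months=int(analysis.get("window_months", 36)),
    )
    n_raw = len(pop)
    pop = cl.apply_run_in(pop, cohort_conf)
    cohort = cl.build_cohort(pop, cohort_conf)
    man.write_table("cohort", cohort.members, rows_in=n_raw)
    ssa = cl.sequence_symmetry(cohort, pop, cohort_conf)
    man.write_table(
        "ssa",
        pd.DataFrame([vars(ssa)]),
        rows_in=len(cohort),
    )
    without_c, with_c, chars = cl.split_by_codrug(cohort, pop, codrug)
    man.write_table("population_characteristics", chars, rows_in=len(cohort))
    man.write_table("exposure_summary", cl.exposure_summary(cohort, pop, index_drug))

    subjects = sv.build_survival(
        cohort, pop, cohort_conf, group_ids=set(with_c.members["patient_id"])
    )
    curves = sv.km_estimate(subjects)
    man.write_table(
        "km_curves", pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
    )
    chi2, p = sv.logrank(subjects)
    cox = sv.cox_hr(subjects)
    tests = pd.DataFrame(
        [
            {
                "logrank_chi2": chi2,
                "logrank_p": p,
                "hr": cox.hr,
                "ci_low": cox.ci_low,
                "ci_high": cox.ci_high,
                "wald_p": cox.wald_p,
                "crude_incidence_without_pct": sv.crude_incidence(
                    subjects[~subjects["group"]], horizon
                ),
                "crude_incidence_with_pct": sv.crude_incidence(
                    subjects[subjects["group"]], horizon
                ),
            }
        ]
    )
    man.write_table("survival_tests", tests, rows_in=len(subjects))
    results.update(
        {
            "ssa": ssa,
            "characteristics": chars,
            "survival_tests": tests,
            "cohort_log": {**pop.log, **cohort.log},
            "manifest": str(man.flush()),
        }
    )
    return results
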