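"""Reporting odds ratio (ROR) disproportionality analysis.

For a 2x2 table of reports

=====================  =======  =========
..                      event    no event
exposed (drug listed)     a         b
unexposed                 c         d
=====================  =======  =========

the ROR is ``(a/b)/(c/d)``; its log has Woolf standard error
``sqrt(1/a + 1/b + 1/c + 1/d)``, giving the 95% CI
``exp(ln ROR +/- 1.96 SE)`` and the signed score ``Z = ln ROR / SE`` used
for volcano-style ranking in place of p-values.  When any cell is zero the
Haldane-Anscombe correction adds 0.5 to all four cells and the result is
flagged as corrected.

``signal_scan`` screens every drug against the whole report population;
``interaction_scan`` restricts the population to reports listing an index
drug and screens every co-listed drug, so a protective drug-drug
interaction shows up as a nested ROR below 1.  Concomitance means
co-listing on the same report — spontaneous reports carry no time stamps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pvclaims.errors import EmptyStratumError, UndefinedExposureError
from pvclaims.reports import ReportSet

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts (a, b, c, d): exposure rows, event columns."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalResult:
    """ROR with Woolf 95% CI and signed Z score for one drug."""

    drug: str | None
    n_cases: int
    ror: float
    ci_low: float
    ci_high: float
    z: float
    corrected: bool
    stratum_size: int | None = None


def compute_ror(table: ContingencyTable, drug: str | None = None) -> SignalResult:
    """ROR, Woolf 95% CI and Z from a 2x2 table.

    Raises :class:`UndefinedExposureError` when an exposure margin is empty
    (no exposed or no unexposed reports): the odds ratio is then undefined
    regardless of continuity correction.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedExposureError(
            f"empty exposure margin in table {(table.a, table.b, table.c, table.d)}"
        )
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a / b) / (c / d)
    ln = math.log(ror)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return SignalResult(
        drug=drug,
        n_cases=table.a,
        ror=ror,
        ci_low=math.exp(ln - Z95 * se),
        ci_high=math.exp(ln + Z95 * se),
        z=ln / se,
        corrected=corrected,
    )


def build_table(
    reports: ReportSet,
    exposure_drug: str,
    stratum: pd.Series | np.ndarray | None = None,
) -> ContingencyTable:
    """Count the 2x2 cells for one drug over a stratum (default: all reports).

    Exposure is membership of the generic id in the report's mapped drug
    set; the event flag must already be labelled.
    """
    frame = reports.frame
    if stratum is not None:
        frame = frame[np.asarray(stratum, dtype=bool)]
    if frame.empty:
        return ContingencyTable(0, 0, 0, 0)
    exposed = frame["drugs"].apply(lambda s: exposure_drug in s).to_numpy(bool)
    event = frame["event"].astype(bool).to_numpy()
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return ContingencyTable(a, b, c, d)


def _exposure_matrix(frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Long-form exploded exposure: all drugs and a report x drug bool matrix."""
    drugs_col = frame["drugs"]
    all_drugs = sorted({d for s in drugs_col for d in s})
    index = {d: j for j, d in enumerate(all_drugs)}
    mat = np.zeros((len(frame), len(all_drugs)), dtype=bool)
    for i, s in enumerate(drugs_col):
        for d in s:
            mat[i, index[d]] = True
    return all_drugs, mat


def _scan(frame: pd.DataFrame, min_cases: int, stratum_size: int | None) -> list[SignalResult]:
    all_drugs, mat = _exposure_matrix(frame)
    event = frame["event"].astype(bool).to_numpy()
    n, n_event = len(frame), int(event.sum())
    a_vec = mat[event].sum(axis=0)
    exp_vec = mat.sum(axis=0)
    results = []
    for j, drug in enumerate(all_drugs):
        a = int(a_vec[j])
        if a < min_cases:
            continue
        b = int(exp_vec[j]) - a
        c = n_event - a
        d = n - n_event - b
        try:
            res = compute_ror(ContingencyTable(a, b, c, d), drug=drug)
        except UndefinedExposureError:
            continue
        res.stratum_size = stratum_size
        results.append(res)
    results.sort(key=lambda r: (-abs(r.z), r.drug))
    return results


def signal_scan(
    reports: ReportSet, min_cases: int = 3, add_bh: bool = False
) -> pd.DataFrame:
    """Screen every drug against the full report population.

    Returns one row per drug with at least ``min_cases`` event reports,
    sorted by \\|Z\\| descending — the table behind a volcano plot of
    ln(ROR) against \\|Z\\|.  ``add_bh`` appends Benjamini-Hochberg q-values
    computed from the two-sided normal p of each Z (optional; the primary
    ranking is unadjusted).
    """
    results = _scan(reports.frame, min_cases, None)
    return _results_frame(results, add_bh)


def interaction_scan(
    reports: ReportSet, index_drug: str, min_cases: int = 3, add_bh: bool = False
) -> pd.DataFrame:
    """Screen co-listed drugs within the index-drug report stratum.

    The population is restricted to reports listing ``index_drug``; each
    other drug's 2x2 table is built inside that stratum, so its ROR
    measures how co-exposure shifts the event odds among index-drug
    reports.
    """
    mask = reports.frame["drugs"].apply(lambda s: index_drug in s).to_numpy(bool)
    stratum = reports.frame[mask]
    if stratum.empty:
        raise EmptyStratumError(f"no reports list index drug {index_drug!r}")
    results = [r for r in _scan(stratum, min_cases, len(stratum)) if r.drug != index_drug]
    return _results_frame(results, add_bh)


def _results_frame(results: list[SignalResult], add_bh: bool) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "drug": r.drug,
                "n_cases": r.n_cases,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "z": r.z,
                "corrected": r.corrected,
                "stratum_size": r.stratum_size,
            }
            for r in results
        ],
        columns=[
            "drug",
            "n_cases",
            "ror",
            "ci_low",
            "ci_high",
            "z",
            "corrected",
            "stratum_size",
        ],
    )
    if add_bh and not frame.empty:
        from statsmodels.stats.multitest import multipletests

        p = 2.0 * stats.norm.sf(np.abs(frame["z"]))
        frame["bh_q"] = multipletests(p, method="fdr_bh")[1]
    return frame


def report_proportions(
    reports: ReportSet, drug_a: str, drug_b: str
) -> pd.DataFrame:
    """Event report proportion in the four co-exposure groups.

    Groups are reports listing neither drug, only ``drug_a``, only
    ``drug_b``, or both; each proportion carries an exact (Clopper-Pearson)
    95% binomial CI.  Empty groups are flagged with NaN proportions.
    """
    frame = reports.frame
    has_a = frame["drugs"].apply(lambda s: drug_a in s).to_numpy(bool)
    has_b = frame["drugs"].apply(lambda s: drug_b in s).to_numpy(bool)
    event = frame["event"].astype(bool).to_numpy()
    rows = []
    for label, mask in (
        ("neither", ~has_a & ~has_b),
        (f"{drug_a} only", has_a & ~has_b),
        (f"{drug_b} only", ~has_a & has_b),
        ("both", has_a & has_b),
    ):
        n = int(mask.sum())
        k = int(event[mask].sum())
        if n == 0:
            rows.append((label, 0, 0, np.nan, np.nan, np.nan, True))
            continue
        lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        rows.append((label, n, k, k / n, lo, hi, False))
    return pd.DataFrame(
        rows,
        columns=["group", "n_reports", "n_events", "proportion", "ci_low", "ci_high", "empty"],
    )
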